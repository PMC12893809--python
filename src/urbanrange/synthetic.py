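"""Ground-truth generators: movement tracks, landscapes, nests, model tables.

Every generator is a pure function of its scenario and seed.  Movement uses
exact transition sampling of the stationary processes (no discretization
error), so recovery tests compare fitted parameters against clean truth.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from shapely.geometry import Polygon, box
from shapely.ops import unary_union

from .geo import LocalProjection
from .habitat import HABITAT_CLASSES, Raster
from .tracking import Fix, Track

#: default projection centre (a mid-latitude European city)
DEFAULT_LON0, DEFAULT_LAT0 = 13.4, 52.5


# ---------------------------------------------------------------------------
# movement tracks


@dataclass
class TrackScenario:
    individual_id: str = "SYN1"
    sigma2: float = 1.0e6  # m^2 per axis
    tau_pos: float = 86400.0  # s
    tau_vel: float = 0.0  # s; > 0 gives the velocity-correlated process
    nest: tuple[float, float] = (0.0, 0.0)
    onset_day: int | None = None  # day index of emigration; None = resident
    displacement: float = 8000.0  # post-onset centre shift, metres
    n_days: int = 120
    start_date: dt.date = dt.date(2023, 6, 1)
    hatch_date: dt.date = dt.date(2023, 4, 15)
    day_window_utc: tuple[float, float] = (3.0, 20.0)  # hours of day with fixes
    interval_choices_s: tuple[float, ...] = (300.0, 900.0, 3600.0, 14400.0)
    gap_windows: tuple[tuple[int, int], ...] = ()  # (start_day, end_day) inclusive
    qc_violation_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.onset_day is not None and self.onset_day >= self.n_days:
            raise ValueError("onset_day must be < n_days")
        if any(i <= 0 for i in self.interval_choices_s):
            raise ValueError("sampling intervals must be positive")


def _sample_times(s: TrackScenario, rng: np.random.Generator) -> np.ndarray:
    """Fix epochs (seconds from start) on an irregular daytime schedule."""
    gaps = [(a, b) for a, b in s.gap_windows]
    times = []
    for day in range(s.n_days):
        if any(a <= day <= b for a, b in gaps):
            continue
        t = day * 86400.0 + s.day_window_utc[0] * 3600.0
        end = day * 86400.0 + s.day_window_utc[1] * 3600.0
        # one sampling interval per day, emulating duty-cycle reprogramming
        step = float(rng.choice(s.interval_choices_s))
        while t < end:
            times.append(t)
            t += step
    return np.asarray(times)


def _sample_ou(times: np.ndarray, sigma2: float, tau: float, rng) -> np.ndarray:
    """Exact stationary OU sample (one axis) at irregular times."""
    n = len(times)
    z = np.empty(n)
    z[0] = rng.normal(0.0, math.sqrt(sigma2))
    dts = np.diff(times)
    rho = np.exp(-dts / tau)
    sd = np.sqrt(sigma2 * (1.0 - rho**2))
    eps = rng.normal(size=n - 1)
    for i in range(1, n):
        z[i] = rho[i - 1] * z[i - 1] + sd[i - 1] * eps[i - 1]
    return z


def _sample_ouf(times: np.ndarray, sigma2: float, tau_p: float, tau_v: float, rng) -> np.ndarray:
    """Exact stationary position/velocity sample (one axis) at irregular times."""
    F = np.array([[0.0, 1.0], [-1.0 / (tau_p * tau_v), -(1.0 / tau_p + 1.0 / tau_v)]])
    Pinf = sigma2 * np.diag([1.0, 1.0 / (tau_p * tau_v)])
    n = len(times)
    z = np.empty((n, 2))
    z[0] = rng.multivariate_normal(np.zeros(2), Pinf)
    for i in range(1, n):
        Phi = expm(F * (times[i] - times[i - 1]))
        Q = Pinf - Phi @ Pinf @ Phi.T
        # symmetrize against roundoff before the Cholesky-free draw
        Q = 0.5 * (Q + Q.T) + 1e-12 * np.eye(2) * sigma2
        z[i] = Phi @ z[i - 1] + rng.multivariate_normal(np.zeros(2), Q)
    return z[:, 0]


def simulate_track(
    s: TrackScenario, projection: LocalProjection | None = None
) -> tuple[Track, dict]:
    """Generate a track; returns (track, truth dict)."""
    rng = np.random.default_rng(s.seed)
    if projection is None:
        projection = LocalProjection(DEFAULT_LON0, DEFAULT_LAT0)
    times = _sample_times(s, rng)
    if len(times) == 0:
        raise ValueError("scenario produced no fixes")

    if s.tau_vel > 0:
        dx = _sample_ouf(times, s.sigma2, s.tau_pos, s.tau_vel, rng)
        dy = _sample_ouf(times, s.sigma2, s.tau_pos, s.tau_vel, rng)
    else:
        dx = _sample_ou(times, s.sigma2, s.tau_pos, rng)
        dy = _sample_ou(times, s.sigma2, s.tau_pos, rng)

    cx = np.full(len(times), s.nest[0])
    cy = np.full(len(times), s.nest[1])
    if s.onset_day is not None:
        angle = rng.uniform(0, 2 * math.pi)
        shift = (s.displacement * math.cos(angle), s.displacement * math.sin(angle))
        post = times >= s.onset_day * 86400.0
        cx[post] += shift[0]
        cy[post] += shift[1]
    else:
        shift = (0.0, 0.0)

    x = cx + dx
    y = cy + dy
    lon, lat = projection.inverse(x, y)

    n = len(times)
    bad = rng.random(n) < s.qc_violation_rate
    hdop = np.where(bad & (rng.random(n) < 0.5), rng.uniform(4.5, 9.0, n), rng.uniform(0.6, 3.5, n))
    sats = np.where(bad & (hdop <= 4.0), rng.integers(3, 5, n), rng.integers(5, 13, n))

    t0 = dt.datetime.combine(s.start_date, dt.time(0, 0), tzinfo=dt.timezone.utc)
    fixes = [
        Fix(
            individual_id=s.individual_id,
            timestamp=t0 + dt.timedelta(seconds=float(ti)),
            lon=float(lo), lat=float(la), x=float(xi), y=float(yi),
            hdop=float(h), n_satellites=int(ns),
        )
        for ti, lo, la, xi, yi, h, ns in zip(times, lon, lat, x, y, hdop, sats)
    ]
    track = Track(s.individual_id, fixes, nest=s.nest, hatch_date=s.hatch_date,
                  projection=projection)
    truth = {
        "sigma2": s.sigma2, "tau_pos": s.tau_pos, "tau_vel": s.tau_vel,
        "onset_date": (s.start_date + dt.timedelta(days=s.onset_day)).isoformat()
        if s.onset_day is not None else None,
        "centre_shift": shift, "n_fixes": len(fixes),
    }
    return track, truth


# ---------------------------------------------------------------------------
# landscapes


@dataclass
class LandscapeScenario:
    extent: tuple[float, float] = (10_000.0, 10_000.0)  # metres
    cell: float = 50.0
    field_range_m: float = 500.0  # smoothing length of the random fields
    sills: dict = field(default_factory=lambda: {
        "tree_cover": 500.0, "imperviousness": 700.0,
        "pop_density": 900.0, "human_footprint": 9.0,
    })
    means: dict = field(default_factory=lambda: {
        "tree_cover": 35.0, "imperviousness": 45.0,
        "pop_density": 60.0, "human_footprint": 25.0,
    })
    n_habitat_seeds_per_class: int = 6
    water_fraction: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.extent
        if abs(w / self.cell - round(w / self.cell)) > 1e-9 or abs(
            h / self.cell - round(h / self.cell)
        ) > 1e-9:
            raise ValueError("extent must be divisible by cell size")


def _gaussian_field(shape, range_cells: float, rng) -> np.ndarray:
    """Unit-variance smooth Gaussian random field via filtered white noise."""
    from scipy.ndimage import gaussian_filter

    white = rng.normal(size=shape)
    f = gaussian_filter(white, sigma=range_cells, mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


def simulate_landscape(s: LandscapeScenario):
    """Returns (rasters dict incl. 'habitat_type', habitat polygons, water polygons)."""
    rng = np.random.default_rng(s.seed)
    n_cols = int(round(s.extent[0] / s.cell))
    n_rows = int(round(s.extent[1] / s.cell))
    origin = (0.0, s.extent[1])
    range_cells = s.field_range_m / s.cell

    rasters: dict[str, Raster] = {}
    clips = {"tree_cover": (0.0, 100.0), "imperviousness": (0.0, 100.0),
             "pop_density": (0.0, None), "human_footprint": (0.0, 50.0)}
    for name, sill in s.sills.items():
        f = _gaussian_field((n_rows, n_cols), range_cells, rng)
        vals = s.means[name] + math.sqrt(sill) * f
        lo, hi = clips.get(name, (None, None))
        vals = np.clip(vals, lo, hi)
        rasters[name] = Raster(origin, s.cell, vals, kind="continuous")

    # habitat classes: nearest seeded centre with noisy distances (organic patches)
    n_classes = len(HABITAT_CLASSES)
    seeds_xy = rng.uniform(0, 1, (n_classes * s.n_habitat_seeds_per_class, 2))
    seeds_xy *= np.array([n_cols, n_rows])
    seed_class = np.repeat(np.arange(n_classes), s.n_habitat_seeds_per_class)
    cols, rows = np.meshgrid(np.arange(n_cols) + 0.5, np.arange(n_rows) + 0.5)
    noise = 0.15 * n_cols * _gaussian_field((n_rows, n_cols), range_cells, rng)
    d = np.full((n_rows, n_cols), np.inf)
    codes = np.zeros((n_rows, n_cols), dtype=np.int64)
    for (sx, sy), cls_ in zip(seeds_xy, seed_class):
        dist = np.hypot(cols - sx, rows - sy) + noise * (0.5 + 0.5 * (cls_ % 2))
        closer = dist < d
        d[closer] = dist[closer]
        codes[closer] = cls_
    habitat = Raster(origin, s.cell, codes, kind="categorical")
    rasters["habitat_type"] = habitat

    water_field = _gaussian_field((n_rows, n_cols), 2 * range_cells, rng)
    thresh = np.quantile(water_field, 1.0 - s.water_fraction)
    water_mask = water_field > thresh
    water_polys = _mask_to_polygons(water_mask, habitat)

    habitat_polys = []
    for code in range(n_classes):
        polys = _mask_to_polygons(codes == code, habitat)
        habitat_polys.extend((code, p) for p in polys)
    return rasters, habitat_polys, water_polys


def _mask_to_polygons(mask: np.ndarray, ref: Raster) -> list[Polygon]:
    if not mask.any():
        return []
    x0, y1 = ref.origin
    c = ref.cell_size
    rows, cols = np.nonzero(mask)
    boxes = [
        box(x0 + j * c, y1 - (i + 1) * c, x0 + (j + 1) * c, y1 - i * c)
        for i, j in zip(rows, cols)
    ]
    merged = unary_union(boxes)
    if isinstance(merged, Polygon):
        return [merged]
    return [g for g in merged.geoms if isinstance(g, Polygon)]


def region_polygon(s: LandscapeScenario) -> Polygon:
    return box(0.0, 0.0, s.extent[0], s.extent[1])


# ---------------------------------------------------------------------------
# breeding sites


def simulate_breeding_sites(
    rasters: dict[str, Raster],
    coefficients: dict[str, float],
    n_presence: int,
    seed: int = 0,
) -> tuple[np.ndarray, Raster]:
    """Sample nest cells with probability prop. to exp(coef . covariates).

    Continuous layers enter min/max-normalized to [0,1]; categorical terms
    use keys like ``habitat_type:4`` (indicator for code 4).  Returns
    (points (n,2), ground-truth log-suitability raster).
    """
    ref = next(iter(rasters.values()))
    eta = np.zeros(ref.values.shape)
    for key, coef in coefficients.items():
        if ":" in key:
            name, code = key.split(":")
            layer = rasters[name]
            eta += coef * (layer.values == int(code))
        else:
            v = rasters[key].values.astype(float)
            rng_v = v.max() - v.min()
            if rng_v > 0:
                eta += coef * (v - v.min()) / rng_v
    p = np.exp(eta - eta.max()).ravel()
    tot = p.sum()
    if tot <= 0:
        raise ValueError("all-zero sampling probabilities")
    p /= tot
    rng = np.random.default_rng(seed)
    idx = rng.choice(p.size, size=n_presence, replace=False, p=p)
    rows, cols = np.unravel_index(idx, eta.shape)
    cx, cy = ref.cell_centres()
    pts = np.column_stack([cx[cols], cy[rows]])
    truth = Raster(ref.origin, ref.cell_size, eta, kind="continuous")
    return pts, truth


# ---------------------------------------------------------------------------
# foraging-area model tables


def simulate_tfa_table(
    n_individuals: int = 40,
    tfa_per_ind: int = 3,
    beta: tuple[float, float] = (4.0, -0.02),
    sigma2_u: float = 0.25,
    family: str = "poisson",
    sigma2_e: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Rows {individual_id, pop_density, response} drawn from the GLMM.

    Population densities are log-uniform on [1, 300] inhabitants/ha.  For
    the Poisson family the linear predictor uses the raw density; for the
    Gaussian family the model is linear in log density with log response.
    """
    rng = np.random.default_rng(seed)
    n = n_individuals * tfa_per_ind
    ind = np.repeat([f"ID{i:03d}" for i in range(n_individuals)], tfa_per_ind)
    dens = np.exp(rng.uniform(math.log(1.0), math.log(300.0), n))
    u = rng.normal(0.0, math.sqrt(sigma2_u), n_individuals)
    u_row = np.repeat(u, tfa_per_ind)
    family = family.lower()
    if family == "poisson":
        eta = beta[0] + beta[1] * dens + u_row
        y = rng.poisson(np.exp(np.clip(eta, -30, 30))).astype(float)
        col = "timespan_days"
    elif family == "gaussian":
        eta = beta[0] + beta[1] * np.log(dens) + u_row
        y = np.exp(eta + rng.normal(0.0, math.sqrt(sigma2_e), n))
        col = "area_ha"
    else:
        raise ValueError(f"unsupported family {family!r}")
    return pd.DataFrame({"individual_id": ind, "pop_density": dens, col: y})
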