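"""Temporal foraging areas: clustering, 95% MCPs, qualification, covariates.

A foraging area is a spatially restricted cluster of fixes inside an
individual's core range, delineated as the 95% minimum convex polygon and
kept only if it holds at least 30 fixes spanning at least 10 days.  The
manual habitat-based grouping of the original workflow is replaced by
density-based clustering with optional habitat-polygon splitting.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

from .habitat import Raster
from .tracking import Fix

log = logging.getLogger(__name__)

CLUSTER_EPS_M = 150.0
CLUSTER_MIN_PTS = 10
MIN_FIXES = 30
MIN_PERIOD_DAYS = 10


@dataclass
class ForagingCluster:
    individual_id: str
    fixes: list[Fix]
    habitat_label: int | str | None = None
    mcp: Polygon | None = None
    area_ha: float | None = None
    timespan_days: float | None = None
    mean_pop_density: float | None = None
    qualified: bool | None = None
    rejection_reasons: list[str] = field(default_factory=list)

    @property
    def xy(self) -> np.ndarray:
        return np.array([(f.x, f.y) for f in self.fixes], dtype=float).reshape(-1, 2)

    @property
    def first_fix(self) -> dt.datetime:
        return min(f.timestamp for f in self.fixes)

    @property
    def last_fix(self) -> dt.datetime:
        return max(f.timestamp for f in self.fixes)


def cluster_fixes(
    fixes: list[Fix],
    eps: float = CLUSTER_EPS_M,
    min_pts: int = CLUSTER_MIN_PTS,
    habitat_polygons: list[tuple[object, Polygon]] | None = None,
) -> list[ForagingCluster]:
    """Density-connected components of fixes; noise fixes left unassigned.

    ``habitat_polygons`` is an optional list of (label, polygon); when given,
    each component is split by the habitat polygon containing each fix.
    """
    if not fixes:
        return []
    from sklearn.cluster import DBSCAN

    xy = np.array([(f.x, f.y) for f in fixes])
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(xy)

    groups: dict[tuple, list[Fix]] = {}
    for f, lab in zip(fixes, labels):
        if lab < 0:
            continue
        key: tuple
        if habitat_polygons is not None:
            hab = _habitat_of(f, habitat_polygons)
            key = (int(lab), hab)
        else:
            key = (int(lab), None)
        groups.setdefault(key, []).append(f)

    out = []
    for (lab, hab), fx in sorted(groups.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))):
        out.append(ForagingCluster(fx[0].individual_id, fx, habitat_label=hab))
    return out


def _habitat_of(fix: Fix, habitat_polygons) -> object:
    from shapely.geometry import Point

    p = Point(fix.x, fix.y)
    for label, poly in habitat_polygons:
        if poly.covers(p):
            return label
    return None


def mcp95(
    points: np.ndarray,
    fraction: float = 0.95,
    order: np.ndarray | None = None,
) -> tuple[Polygon, float]:
    """95% minimum convex polygon: trim the ceil(5%) of points farthest from
    the centroid, then take the convex hull.  Returns (polygon, area m^2).

    ``order`` (e.g. timestamps as sortable values) breaks distance ties:
    among equidistant points the earlier one is removed first.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 5:
        raise ValueError(f"need >= 5 points, got {n}")
    centroid = points.mean(axis=0)
    d = np.hypot(points[:, 0] - centroid[0], points[:, 1] - centroid[1])
    # guard against float artifacts like (1 - 0.95) * 60 = 3.0000000000000027
    n_drop = math.ceil((1.0 - fraction) * n - 1e-9)
    if order is None:
        order = np.arange(n)
    # farthest first; ties by earlier order value first
    rank = sorted(range(n), key=lambda i: (-d[i], order[i]))
    drop = set(rank[:n_drop])
    kept = points[[i for i in range(n) if i not in drop]]

    from shapely.geometry import MultiPoint

    hull = MultiPoint(kept).convex_hull
    if hull.geom_type != "Polygon" or hull.area <= 0:
        raise ValueError("degenerate 95% MCP: remaining points are collinear")
    return hull, float(hull.area)


def qualify_tfa(
    cluster: ForagingCluster,
    min_fixes: int = MIN_FIXES,
    min_period_days: int = MIN_PERIOD_DAYS,
) -> tuple[bool, list[str]]:
    """Accept iff >= min_fixes fixes AND the date span covers >= min_period_days."""
    if not cluster.fixes:
        raise ValueError("empty cluster")
    reasons = []
    if len(cluster.fixes) < min_fixes:
        reasons.append(f"only {len(cluster.fixes)} fixes < {min_fixes}")
    dates = [f.date for f in cluster.fixes]
    period = (max(dates) - min(dates)).days + 1
    if period < min_period_days:
        reasons.append(f"period {period} days < {min_period_days}")
    return (not reasons), reasons


def occupancy_timespan(cluster: ForagingCluster, central: bool = True) -> float:
    """Occupancy span in days as the central 95% interquantile range of
    fix timestamps (linear-interpolated quantiles).

    ``central=False`` instead returns the 0.95 quantile of time since the
    first fix (the alternative reading).
    """
    if len(cluster.fixes) < 2:
        raise ValueError("need >= 2 fixes")
    t0 = cluster.first_fix
    secs = np.array([(f.timestamp - t0).total_seconds() for f in cluster.fixes])
    if central:
        lo, hi = np.quantile(secs, [0.025, 0.975])
        span = hi - lo
    else:
        span = float(np.quantile(secs, 0.95))
    return float(span) / 86400.0


def mean_covariate(polygon: Polygon, raster: Raster) -> float:
    """Mean of raster cells whose centres fall inside the polygon."""
    cx, cy = raster.cell_centres()
    xs, ys = np.meshgrid(cx, cy)
    from .geo import points_in_polygon

    minx, miny, maxx, maxy = polygon.bounds
    coarse = (xs >= minx) & (xs <= maxx) & (ys >= miny) & (ys <= maxy)
    vals = raster.values
    mask = np.zeros_like(coarse)
    idx = np.flatnonzero(coarse.ravel())
    if idx.size:
        inside = points_in_polygon(xs.ravel()[idx], ys.ravel()[idx], polygon)
        mask.ravel()[idx] = inside
    if raster.nodata is not None:
        mask &= vals != raster.nodata
    mask &= np.isfinite(vals.astype(float))
    if not mask.any():
        raise ValueError("polygon covers no raster cell centres")
    return float(vals[mask].mean())


def characterize(
    cluster: ForagingCluster,
    pop_density: Raster | None = None,
    central_quantile: bool = True,
) -> ForagingCluster:
    """Fill MCP, area, occupancy span and mean population density in place."""
    order = np.array([f.timestamp.timestamp() for f in cluster.fixes])
    poly, area_m2 = mcp95(cluster.xy, order=order)
    cluster.mcp = poly
    cluster.area_ha = area_m2 / 1e4
    cluster.timespan_days = occupancy_timespan(cluster, central=central_quantile)
    if pop_density is not None:
        cluster.mean_pop_density = mean_covariate(poly, pop_density)
    ok, reasons = qualify_tfa(cluster)
    cluster.qualified = ok
    cluster.rejection_reasons = reasons
    return cluster


def extract_tfas(
    individual_id: str,
    fixes: list[Fix],
    cfr_polygons: list[Polygon],
    pop_density: Raster | None = None,
    eps: float = CLUSTER_EPS_M,
    min_pts: int = CLUSTER_MIN_PTS,
    habitat_polygons=None,
) -> list[ForagingCluster]:
    """Full TFA pass for one individual: restrict to CFR, cluster, qualify."""
    from .geo import points_in_polygon

    if cfr_polygons:
        xy = np.array([(f.x, f.y) for f in fixes]).reshape(-1, 2)
        inside = np.zeros(len(fixes), dtype=bool)
        for poly in cfr_polygons:
            inside |= points_in_polygon(xy[:, 0], xy[:, 1], poly)
        fixes = [f for f, m in zip(fixes, inside) if m]
    clusters = cluster_fixes(fixes, eps=eps, min_pts=min_pts, habitat_polygons=habitat_polygons)
    out = []
    for c in clusters:
        try:
            characterize(c, pop_density=pop_density)
        except ValueError as exc:
            log.info("cluster of %s skipped: %s", individual_id, exc)
            continue
        out.append(c)
    return [c for c in out if c.qualified]
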