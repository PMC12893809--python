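"""GPS fix ingestion, quality control, daylight filtering and spatial clipping.

Input is a tracker CSV with columns ``individual_id, timestamp, lon, lat,
hdop, n_satellites`` (ISO-8601 UTC timestamps) plus an optional nest-metadata
CSV ``individual_id, nest_lon, nest_lat, hatch_date``.  All downstream work
happens in a local metric projection (see :mod:`urbanrange.geo`).
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .geo import LocalProjection, points_in_polygon

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("individual_id", "timestamp", "lon", "lat", "hdop", "n_satellites")

#: QC defaults: drop fixes with hdop > 4 or fewer than 5 satellites.
HDOP_MAX = 4.0
MIN_SATELLITES = 5
#: Daytime incl. nautical twilight = solar elevation above -12 degrees.
MIN_SOLAR_ELEVATION = -12.0
MIN_TRACKING_DAYS = 30


class SchemaError(ValueError):
    """Raised when a required input column is missing."""


@dataclass(frozen=True)
class Fix:
    individual_id: str
    timestamp: dt.datetime  # tz-aware UTC
    lon: float
    lat: float
    x: float
    y: float
    hdop: float
    n_satellites: int

    @property
    def date(self) -> dt.date:
        return self.timestamp.date()


@dataclass
class Track:
    """Time-ordered fixes of one individual, with nest metadata."""

    individual_id: str
    fixes: list[Fix]
    nest: tuple[float, float] | None = None  # metres, working projection
    hatch_date: dt.date | None = None
    projection: LocalProjection | None = None

    def __post_init__(self) -> None:
        ts = [f.timestamp for f in self.fixes]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("fixes must have strictly increasing timestamps")
        if any(f.individual_id != self.individual_id for f in self.fixes):
            raise ValueError("all fixes must share the track's individual_id")

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def xy(self) -> np.ndarray:
        return np.array([(f.x, f.y) for f in self.fixes], dtype=float).reshape(-1, 2)

    @property
    def times(self) -> np.ndarray:
        """Seconds since the first fix."""
        if not self.fixes:
            return np.empty(0)
        t0 = self.fixes[0].timestamp
        return np.array([(f.timestamp - t0).total_seconds() for f in self.fixes])

    @property
    def dates(self) -> list[dt.date]:
        return [f.date for f in self.fixes]

    def with_fixes(self, fixes: Sequence[Fix]) -> "Track":
        return Track(self.individual_id, list(fixes), self.nest, self.hatch_date, self.projection)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": [f.individual_id for f in self.fixes],
                "timestamp": [f.timestamp.isoformat().replace("+00:00", "Z") for f in self.fixes],
                "lon": [f.lon for f in self.fixes],
                "lat": [f.lat for f in self.fixes],
                "hdop": [f.hdop for f in self.fixes],
                "n_satellites": [f.n_satellites for f in self.fixes],
                "x": [f.x for f in self.fixes],
                "y": [f.y for f in self.fixes],
            }
        )


def read_fixes(
    path: str | Path,
    id_map: Mapping[str, str] | None = None,
    projection: LocalProjection | None = None,
) -> dict[str, Track]:
    """Parse a tracker CSV into per-individual :class:`Track` objects.

    ``id_map`` renames source columns to the canonical schema before
    validation.  Duplicate timestamps within an individual keep the first
    occurrence (warned).  If ``projection`` is None a transverse-Mercator
    projection centred on the fix centroid is used.
    """
    df = pd.read_csv(path)
    if id_map:
        df = df.rename(columns=dict(id_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    except (ValueError, TypeError):
        # locate the offending row for a useful message
        for i, v in enumerate(df["timestamp"]):
            try:
                pd.to_datetime(v, utc=True)
            except (ValueError, TypeError):
                raise ValueError(f"unparseable timestamp {v!r} at data row {i + 1}") from None
        raise

    bad_lat = ~df["lat"].between(-90, 90)
    bad_lon = ~df["lon"].between(-180, 180)
    if bad_lat.any() or bad_lon.any():
        raise ValueError("coordinates outside valid lon/lat bounds")

    if projection is None:
        projection = LocalProjection(lon0=float(df["lon"].mean()), lat0=float(df["lat"].mean()))

    x, y = projection.forward(df["lon"].to_numpy(), df["lat"].to_numpy())
    df = df.assign(x=x, y=y)

    tracks: dict[str, Track] = {}
    for ind, g in df.groupby("individual_id", sort=True):
        g = g.sort_values("timestamp", kind="stable")
        dup = g["timestamp"].duplicated()
        if dup.any():
            log.warning(
                "individual %s: %d duplicate timestamp(s) collapsed to first occurrence",
                ind,
                int(dup.sum()),
            )
            g = g[~dup]
        fixes = [
            Fix(
                individual_id=str(ind),
                timestamp=ts.to_pydatetime(),
                lon=float(r.lon),
                lat=float(r.lat),
                x=float(r.x),
                y=float(r.y),
                hdop=float(r.hdop),
                n_satellites=int(r.n_satellites),
            )
            for ts, r in zip(g["timestamp"], g.itertuples())
        ]
        tracks[str(ind)] = Track(str(ind), fixes, projection=projection)
    return tracks


def attach_nests(
    tracks: dict[str, Track], nests_path: str | Path, projection: LocalProjection
) -> dict[str, Track]:
    """Join nest coordinates and hatch dates onto tracks (in place and returned)."""
    meta = pd.read_csv(nests_path)
    for col in ("individual_id", "nest_lon", "nest_lat", "hatch_date"):
        if col not in meta.columns:
            raise SchemaError(f"missing required column(s): {col}")
    for r in meta.itertuples():
        ind = str(r.individual_id)
        if ind in tracks:
            nx, ny = projection.forward(float(r.nest_lon), float(r.nest_lat))
            tracks[ind].nest = (float(nx), float(ny))
            tracks[ind].hatch_date = pd.Timestamp(r.hatch_date).date()
    return tracks


def qc_filter(track: Track, hdop_max: float = HDOP_MAX, min_sats: int = MIN_SATELLITES) -> Track:
    """Drop imprecise fixes: hdop > hdop_max or n_satellites < min_sats."""
    if not track.fixes:
        raise ValueError("empty track")
    kept = [f for f in track.fixes if f.hdop <= hdop_max and f.n_satellites >= min_sats]
    return track.with_fixes(kept)


def _day_of_year_fraction(t: dt.datetime) -> tuple[int, float]:
    t = t.astimezone(dt.timezone.utc)
    doy = t.timetuple().tm_yday
    hours = t.hour + t.minute / 60.0 + t.second / 3600.0 + t.microsecond / 3.6e9
    return doy, hours


def solar_elevation(lat: float, lon: float, t: dt.datetime) -> float:
    """Geometric solar elevation (degrees above horizon), refraction ignored.

    Low-precision ephemeris: declination and equation of time from the
    fractional-year series; accurate to ~0.1 degrees, ample for a twilight
    threshold applied to wildlife telemetry.
    """
    doy, hours = _day_of_year_fraction(t)
    # fractional year (radians)
    gamma = 2.0 * np.pi / 365.0 * (doy - 1 + (hours - 12.0) / 24.0)
    decl = (
        0.006918
        - 0.399912 * np.cos(gamma)
        + 0.070257 * np.sin(gamma)
        - 0.006758 * np.cos(2 * gamma)
        + 0.000907 * np.sin(2 * gamma)
        - 0.002697 * np.cos(3 * gamma)
        + 0.00148 * np.sin(3 * gamma)
    )
    # equation of time, minutes
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * np.cos(gamma)
        - 0.032077 * np.sin(gamma)
        - 0.014615 * np.cos(2 * gamma)
        - 0.040849 * np.sin(2 * gamma)
    )
    time_offset = eqtime + 4.0 * lon  # minutes
    tst = hours * 60.0 + time_offset  # true solar time, minutes
    ha = np.radians(tst / 4.0 - 180.0)  # hour angle
    phi = np.radians(lat)
    cos_zenith = np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.cos(ha)
    cos_zenith = np.clip(cos_zenith, -1.0, 1.0)
    return float(90.0 - np.degrees(np.arccos(cos_zenith)))


def daylight_filter(track: Track, min_elevation: float = MIN_SOLAR_ELEVATION) -> Track:
    """Keep fixes taken while the sun is above ``min_elevation`` degrees."""
    if not track.fixes:
        raise ValueError("empty track")
    kept = [f for f in track.fixes if solar_elevation(f.lat, f.lon, f.timestamp) >= min_elevation]
    return track.with_fixes(kept)


def clip_and_qualify(
    tracks: dict[str, Track],
    region: Polygon,
    min_tracking_days: int = MIN_TRACKING_DAYS,
) -> dict[str, Track]:
    """Clip fixes to the study region and keep individuals with enough days.

    ``region`` must be in the working projection.  A fix on the boundary is
    inside.  A "tracking day" is a distinct UTC calendar date with at least
    one retained fix.
    """
    if region.area <= 0:
        raise ValueError("degenerate region polygon (zero area)")
    out: dict[str, Track] = {}
    for ind, track in tracks.items():
        if not track.fixes:
            log.info("individual %s excluded: no fixes", ind)
            continue
        xy = track.xy
        mask = points_in_polygon(xy[:, 0], xy[:, 1], region)
        kept = [f for f, m in zip(track.fixes, mask) if m]
        n_days = len({f.date for f in kept})
        if n_days < min_tracking_days:
            log.info(
                "individual %s excluded: %d tracking day(s) < %d", ind, n_days, min_tracking_days
            )
            continue
        out[ind] = track.with_fixes(kept)
    return out


def write_fixes(tracks: dict[str, Track], path: str | Path) -> None:
    """Write tracks back to the canonical CSV dialect (with x/y columns)."""
    frames = [t.to_frame() for _, t in sorted(tracks.items())]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=list(REQUIRED_COLUMNS) + ["x", "y"]
    )
    df.to_csv(path, index=False)
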