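"""Natal-dispersal onset detection and track truncation.

Onset is the first calendar day on which every fix lies outside the circular
parental territory, with no fix back inside the circle during the following
return window.  Days without any fix inside the window count as non-returns
(logged), since absence of data cannot veto an emigration.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass

from .tracking import Track

log = logging.getLogger(__name__)

TERRITORY_RADIUS_M = 1000.0
RETURN_WINDOW_DAYS = 7
MAX_AGE_DAYS = 730


@dataclass(frozen=True)
class DispersalResult:
    individual_id: str
    onset_date: dt.date | None
    territory_radius: float = TERRITORY_RADIUS_M
    return_window: int = RETURN_WINDOW_DAYS
    max_age: int = MAX_AGE_DAYS

    @property
    def dispersed(self) -> bool:
        return self.onset_date is not None


def territory_area_km2(radius_m: float = TERRITORY_RADIUS_M) -> float:
    """Area of the circular parental territory in square kilometres."""
    return math.pi * radius_m**2 / 1e6


def detect_onset(
    track: Track,
    nest: tuple[float, float] | None = None,
    radius: float = TERRITORY_RADIUS_M,
    return_window: int = RETURN_WINDOW_DAYS,
) -> DispersalResult:
    """Find the first all-outside day with no return within ``return_window`` days."""
    if not track.fixes:
        raise ValueError("empty track")
    if nest is None:
        nest = track.nest
    if nest is None:
        raise ValueError("nest location required")
    nx, ny = nest

    by_day: dict[dt.date, list[bool]] = {}
    for f in track.fixes:
        outside = math.hypot(f.x - nx, f.y - ny) > radius
        by_day.setdefault(f.date, []).append(outside)

    days = sorted(by_day)
    day_outside = {d: all(v) for d, v in by_day.items()}

    for d in days:
        if not day_outside[d]:
            continue
        returned = False
        gap_days = 0
        for k in range(1, return_window + 1):
            dk = d + dt.timedelta(days=k)
            if dk not in by_day:
                gap_days += 1
                continue
            if not day_outside[dk]:
                returned = True
                break
        if returned:
            continue
        if gap_days:
            log.info(
                "individual %s: onset %s accepted with %d gap day(s) in the return window",
                track.individual_id,
                d,
                gap_days,
            )
        return DispersalResult(track.individual_id, d, radius, return_window)
    return DispersalResult(track.individual_id, None, radius, return_window)


def dispersal_window(
    track: Track, result: DispersalResult, max_age: int = MAX_AGE_DAYS
) -> Track:
    """Truncate to fixes from onset_date up to an age of ``max_age`` days."""
    if result.onset_date is None:
        raise ValueError(
            f"individual {track.individual_id}: no dispersal onset detected; exclude individual"
        )
    if track.hatch_date is None:
        raise ValueError("hatch_date required to bound the track by age")
    kept = [
        f
        for f in track.fixes
        if f.date >= result.onset_date and (f.date - track.hatch_date).days <= max_age
    ]
    return track.with_fixes(kept)
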