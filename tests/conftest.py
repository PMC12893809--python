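import datetime as dt

import numpy as np
import pytest

from urbanrange.tracking import Fix, Track

UTC = dt.timezone.utc
T0 = dt.datetime(2023, 6, 1, 8, 0, tzinfo=UTC)


def make_fix(x, y, ts, ind="A", hdop=1.0, sats=8, lon=0.0, lat=0.0):
    return Fix(individual_id=ind, timestamp=ts, lon=lon, lat=lat, x=x, y=y,
               hdop=hdop, n_satellites=sats)


def make_track(xy, times_s=None, ind="A", nest=(0.0, 0.0), hatch=dt.date(2023, 4, 1),
               t0=T0, hdop=None, sats=None):
    """Track from an (n,2) array and per-fix offsets in seconds."""
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    if times_s is None:
        times_s = 3600.0 * np.arange(n)
    fixes = [
        make_fix(
            xy[i, 0], xy[i, 1], t0 + dt.timedelta(seconds=float(times_s[i])), ind=ind,
            hdop=1.0 if hdop is None else hdop[i],
            sats=8 if sats is None else sats[i],
        )
        for i in range(n)
    ]
    return Track(ind, fixes, nest=nest, hatch_date=hatch)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def ray_cast_inside(px, py, poly_coords):
    """Independent even-odd point-in-polygon test (boundary-tolerant)."""
    inside = False
    n = len(poly_coords)
    for i in range(n):
        x1, y1 = poly_coords[i]
        x2, y2 = poly_coords[(i + 1) % n]
        # on-edge check
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        if abs(cross) < 1e-9 and min(x1, x2) - 1e-9 <= px <= max(x1, x2) + 1e-9 \
                and min(y1, y2) - 1e-9 <= py <= max(y1, y2) + 1e-9:
            return True
        if (y1 > py) != (y2 > py):
            xin = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xin:
                inside = not inside
    return inside
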