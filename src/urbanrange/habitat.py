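"""Raster predictor handling: rescaling, focal aggregation, collinearity.

Rasters are plain in-memory grids with an Arc/Info ASCII-grid text format
for I/O (row 0 = northernmost; half-open cells).  Continuous layers rescale
by area-weighted block means, categorical layers by majority vote.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

TARGET_CELL_M = 50.0
FOCAL_RADII_M = {"local": 50.0, "territory": 200.0, "home_range": 1000.0}
COLLINEARITY_R = 0.7

HABITAT_CLASSES = {
    0: "others",
    1: "residential",
    2: "urban_mixed",
    3: "natural_mixed",
    4: "city_parks",
    5: "cemeteries",
}


@dataclass
class Raster:
    """Single-band grid; origin is the north-west corner (metres)."""

    origin: tuple[float, float]  # (x_west, y_north)
    cell_size: float
    values: np.ndarray  # shape (n_rows, n_cols); row 0 northernmost
    nodata: float | None = None
    kind: str = "continuous"  # or "categorical"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.kind == "categorical" and not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("categorical rasters need integer codes")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        x0, y1 = self.origin
        return (x0, y1 - self.n_rows * self.cell_size, x0 + self.n_cols * self.cell_size, y1)

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """(x centres west->east, y centres north->south) matching value rows."""
        x0, y1 = self.origin
        cx = x0 + self.cell_size * (np.arange(self.n_cols) + 0.5)
        cy = y1 - self.cell_size * (np.arange(self.n_rows) + 0.5)
        return cx, cy

    def same_grid(self, other: "Raster") -> bool:
        return (
            self.values.shape == other.values.shape
            and abs(self.cell_size - other.cell_size) < 1e-9
            and abs(self.origin[0] - other.origin[0]) < 1e-6
            and abs(self.origin[1] - other.origin[1]) < 1e-6
        )

    # --- text I/O (Arc/Info ASCII grid) ---

    def write_ascii(self, path: str | Path) -> None:
        x0, y0 = self.origin[0], self.origin[1] - self.n_rows * self.cell_size
        nodata = self.nodata if self.nodata is not None else -9999
        with open(path, "w") as fh:
            fh.write(f"ncols {self.n_cols}\n")
            fh.write(f"nrows {self.n_rows}\n")
            fh.write(f"xllcorner {x0!r}\n")
            fh.write(f"yllcorner {y0!r}\n")
            fh.write(f"cellsize {self.cell_size!r}\n")
            fh.write(f"NODATA_value {nodata}\n")
            fmt = "%d" if self.kind == "categorical" else "%.10g"
            np.savetxt(fh, self.values, fmt=fmt)

    @classmethod
    def read_ascii(cls, path: str | Path, kind: str = "continuous") -> "Raster":
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            values = np.loadtxt(fh)
        values = np.atleast_2d(values)
        if kind == "categorical":
            values = values.astype(np.int64)
        n_rows, cell = int(header["nrows"]), header["cellsize"]
        origin = (header["xllcorner"], header["yllcorner"] + n_rows * cell)
        return cls(origin, cell, values, nodata=header.get("nodata_value"), kind=kind)


def resample_raster(r: Raster, target_cell: float = TARGET_CELL_M) -> Raster:
    """Rescale to target_cell: block mean (continuous) or majority (categorical).

    General (non-integer) ratios use exact 1-D overlap weights along each
    axis; categorical majority is by overlap area with ties to the lowest
    code.
    """
    if target_cell <= 0:
        raise ValueError("target_cell must be positive")
    if r.values.size == 0:
        raise ValueError("empty raster")
    if abs(target_cell - r.cell_size) < 1e-12:
        return replace(r, values=r.values.copy())

    width = r.n_cols * r.cell_size
    height = r.n_rows * r.cell_size
    n_cols = max(1, int(round(width / target_cell)))
    n_rows = max(1, int(round(height / target_cell)))

    wx = _overlap_weights(r.n_cols, r.cell_size, n_cols, target_cell)
    wy = _overlap_weights(r.n_rows, r.cell_size, n_rows, target_cell)

    if r.kind == "categorical":
        codes = np.unique(r.values)
        best_val = np.zeros((n_rows, n_cols), dtype=r.values.dtype)
        best_w = np.full((n_rows, n_cols), -1.0)
        for code in codes:  # lowest code first, strict > keeps ties at lowest
            ind = (r.values == code).astype(float)
            w = wy @ ind @ wx.T
            better = w > best_w + 1e-12
            best_val[better] = code
            best_w[better] = w[better]
        return Raster(r.origin, target_cell, best_val, nodata=r.nodata, kind="categorical")

    vals = r.values.astype(float)
    if r.nodata is not None:
        valid = (vals != r.nodata).astype(float)
        vals = np.where(valid > 0, vals, 0.0)
    else:
        valid = np.ones_like(vals)
    num = wy @ (vals * valid) @ wx.T
    den = wy @ valid @ wx.T
    out = np.where(den > 0, num / np.maximum(den, 1e-300), r.nodata if r.nodata is not None else np.nan)
    return Raster(r.origin, target_cell, out, nodata=r.nodata, kind="continuous")


def _overlap_weights(n_src: int, src_cell: float, n_dst: int, dst_cell: float) -> np.ndarray:
    """(n_dst, n_src) matrix of 1-D overlap lengths between cell intervals."""
    src_lo = np.arange(n_src) * src_cell
    src_hi = src_lo + src_cell
    dst_lo = np.arange(n_dst) * dst_cell
    dst_hi = dst_lo + dst_cell
    lo = np.maximum(dst_lo[:, None], src_lo[None, :])
    hi = np.minimum(dst_hi[:, None], src_hi[None, :])
    return np.clip(hi - lo, 0.0, None)


def focal_mean(r: Raster, centre: tuple[float, float], radius: float) -> float:
    """Mean of cells whose centres lie within ``radius`` of ``centre``."""
    cx, cy = r.cell_centres()
    dx2 = (cx - centre[0]) ** 2
    dy2 = (cy - centre[1]) ** 2
    mask = dy2[:, None] + dx2[None, :] <= radius**2
    vals = r.values
    if r.nodata is not None:
        mask &= vals != r.nodata
    if not mask.any():
        raise ValueError("no raster cells within the focal circle")
    return float(vals[mask].astype(float).mean())


def extract_predictors(
    rasters: dict[str, Raster],
    scales: dict[str, str],
    points: np.ndarray,
) -> "pd.DataFrame":
    """Focal-mean predictor values at points; categorical layers sample the
    containing cell and expand to one-hot indicator columns (reference level
    omitted: code 0)."""
    import pandas as pd

    points = np.asarray(points, dtype=float).reshape(-1, 2)
    cols: dict[str, np.ndarray] = {}
    for name, r in rasters.items():
        if r.kind == "categorical":
            codes = np.array([_cell_value(r, p) for p in points])
            levels = sorted(int(c) for c in np.unique(r.values))
            for lev in levels[1:]:  # level 0 (or lowest) is the reference
                cols[f"{name}_{lev}"] = (codes == lev).astype(float)
        else:
            radius = FOCAL_RADII_M[scales.get(name, "local")]
            cols[name] = np.array([focal_mean(r, tuple(p), radius) for p in points])
    return pd.DataFrame(cols)


def _cell_value(r: Raster, p: np.ndarray):
    x0, y1 = r.origin
    col = int((p[0] - x0) // r.cell_size)
    row = int((y1 - p[1]) // r.cell_size)
    row = min(max(row, 0), r.n_rows - 1)
    col = min(max(col, 0), r.n_cols - 1)
    return r.values[row, col]


def collinearity_filter(
    table: "pd.DataFrame",
    scores: dict[str, float],
    threshold: float = COLLINEARITY_R,
) -> list[str]:
    """Greedy Pearson screen: while any |r| > threshold, drop the lower-scored
    member of the worst pair (processed by descending |r|, ties by name).

    ``scores`` maps column name -> univariate model performance (higher is
    better, e.g. cross-validated AUC).  Constant columns are dropped with a
    warning since their correlation is undefined.
    """
    cols = [c for c in table.columns]
    retained = []
    for c in cols:
        if np.std(table[c].to_numpy(dtype=float)) == 0:
            log.warning("constant predictor %s dropped (correlation undefined)", c)
        else:
            retained.append(c)

    while True:
        if len(retained) < 2:
            break
        sub = table[retained].to_numpy(dtype=float)
        r = np.corrcoef(sub, rowvar=False)
        np.fill_diagonal(r, 0.0)
        pairs = []
        for i in range(len(retained)):
            for j in range(i + 1, len(retained)):
                if abs(r[i, j]) > threshold:
                    pairs.append((abs(r[i, j]), retained[i], retained[j]))
        if not pairs:
            break
        pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
        _, a, b = pairs[0]
        drop = a if scores.get(a, 0.0) < scores.get(b, 0.0) else b
        if scores.get(a, 0.0) == scores.get(b, 0.0):
            drop = max(a, b)  # deterministic tie-break by name
        log.info("collinearity: dropping %s (|r|=%.3f with %s)", drop, pairs[0][0], a if drop == b else b)
        retained.remove(drop)
    return retained
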