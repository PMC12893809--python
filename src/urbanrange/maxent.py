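"""Presence/background maximum-entropy habitat suitability modelling.

The model is fit directly as an L1-penalized Gibbs (exponential-family)
density over background points: maximize

    mean_presence(lambda . f) - log(mean_background exp(lambda . f))
        - sum_j beta_j |lambda_j|

by cyclic coordinate-wise proximal Newton updates.  Per-feature penalties
are beta_j = multiplier * s_j / sqrt(m) with s_j the presence standard
deviation of feature j and m the presence count.  Evaluation is by
stratified k-fold cross-validation (AUC, TSS), binarization by the
max-sensitivity-plus-specificity threshold, and area accounting excludes
masked habitat and circular buffers around occupied nests.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .habitat import Raster

log = logging.getLogger(__name__)

FEATURE_COMBOS = {
    "LQPH": ("linear", "quadratic", "product", "hinge"),
    "HP": ("hinge", "product"),
    "H": ("hinge",),
}
BETA_MULTIPLIERS = (1, 2, 3, 4, 5)
MAX_ITER = 2500
DEFAULT_TOL = 1e-5
BACKGROUND_RATIO = 10
BUFFER_RADIUS_M = 1000.0

# presence std floor in the penalty; keeps beta_j > 0 for near-constant features
_S_FLOOR = 1e-3


# ---------------------------------------------------------------------------
# background sampling


def sample_background(
    region: Polygon,
    water: list[Polygon],
    n_presence: int,
    ratio: int = BACKGROUND_RATIO,
    seed: int = 0,
) -> np.ndarray:
    """Uniform random points in region minus water, ratio x n_presence of them."""
    target = ratio * n_presence
    usable = region
    for w in water:
        usable = usable.difference(w)
    if usable.is_empty or usable.area <= 0:
        raise ValueError("region minus water is empty")
    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = usable.bounds
    pts: list[tuple[float, float]] = []
    import shapely

    shapely.prepare(usable)
    while len(pts) < target:
        m = max(2 * (target - len(pts)), 64)
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        ok = shapely.covers(usable, shapely.points(xs, ys))
        for x, y in zip(xs[ok], ys[ok]):
            pts.append((x, y))
            if len(pts) == target:
                break
    return np.array(pts)


# ---------------------------------------------------------------------------
# features


@dataclass(frozen=True)
class FeatureSpec:
    classes: tuple[str, ...] = ("linear", "quadratic", "product", "hinge")
    hinge_knots_per_var: int = 20

    def __post_init__(self) -> None:
        unknown = set(self.classes) - {"linear", "quadratic", "product", "hinge"}
        if unknown:
            raise ValueError(f"unknown feature classes: {unknown}")
        if "hinge" in self.classes and self.hinge_knots_per_var < 2:
            raise ValueError("hinge_knots_per_var must be >= 2")


@dataclass
class FeatureMap:
    """Train-time normalization plus the expansion into the feature basis.

    Continuous covariates are min/max scaled to [0,1] using the training
    range; categorical one-hot indicator columns (detected by name or given
    explicitly) pass through as linear features only.
    """

    spec: FeatureSpec
    continuous: list[str]
    indicator: list[str]
    lo: dict[str, float]
    hi: dict[str, float]
    names: list[str] = field(default_factory=list)

    @classmethod
    def fit(
        cls,
        table: pd.DataFrame,
        spec: FeatureSpec,
        indicator_cols: list[str] | None = None,
    ) -> "FeatureMap":
        if indicator_cols is None:
            indicator_cols = [
                c for c in table.columns
                if set(np.unique(table[c].to_numpy(dtype=float))) <= {0.0, 1.0}
            ]
        continuous, dropped = [], []
        lo, hi = {}, {}
        for c in table.columns:
            if c in indicator_cols:
                continue
            v = table[c].to_numpy(dtype=float)
            a, b = float(v.min()), float(v.max())
            if b - a <= 0:
                dropped.append(c)
                continue
            continuous.append(c)
            lo[c], hi[c] = a, b
        if dropped:
            log.warning("zero-variance covariate(s) dropped: %s", ", ".join(dropped))
        fm = cls(spec, continuous, list(indicator_cols), lo, hi)
        fm.names = fm._feature_names()
        return fm

    def _knots(self) -> np.ndarray:
        k = self.spec.hinge_knots_per_var
        return np.arange(1, k + 1) / (k + 1)

    def _feature_names(self) -> list[str]:
        names = []
        cls = self.spec.classes
        if "linear" in cls:
            names += [f"lin:{c}" for c in self.continuous]
        if "quadratic" in cls:
            names += [f"quad:{c}" for c in self.continuous]
        if "product" in cls:
            names += [f"prod:{a}*{b}" for a, b in itertools.combinations(self.continuous, 2)]
        if "hinge" in cls:
            for c in self.continuous:
                for k in self._knots():
                    names.append(f"hingef:{c}@{k:.4f}")
                for k in self._knots():
                    names.append(f"hinger:{c}@{k:.4f}")
        names += [f"lin:{c}" for c in self.indicator]
        return names

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        xs = {}
        for c in self.continuous:
            v = table[c].to_numpy(dtype=float)
            xs[c] = np.clip((v - self.lo[c]) / (self.hi[c] - self.lo[c]), 0.0, 1.0)
        cols = []
        cls = self.spec.classes
        if "linear" in cls:
            cols += [xs[c] for c in self.continuous]
        if "quadratic" in cls:
            cols += [xs[c] ** 2 for c in self.continuous]
        if "product" in cls:
            cols += [xs[a] * xs[b] for a, b in itertools.combinations(self.continuous, 2)]
        if "hinge" in cls:
            for c in self.continuous:
                x = xs[c]
                for k in self._knots():
                    cols.append(np.maximum(0.0, (x - k) / (1.0 - k)))
                for k in self._knots():
                    cols.append(np.maximum(0.0, (k - x) / k))
        for c in self.indicator:
            cols.append(table[c].to_numpy(dtype=float))
        if not cols:
            return np.empty((len(table), 0))
        return np.column_stack(cols)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class MaxentModel:
    feature_map: FeatureMap
    lam: np.ndarray
    beta_multiplier: float
    betas: np.ndarray
    log_z_mean: float  # log of mean_bg exp(lam.f) at the training background
    z_sum: float  # sum_bg exp(lam.f); normalizer for raw output
    entropy: float  # entropy of the raw distribution over training background
    iterations: int
    converged: bool
    objective: float


def penalized_objective(
    lam: np.ndarray, f_pres: np.ndarray, f_bg: np.ndarray, betas: np.ndarray
) -> float:
    eta_bg = f_bg @ lam
    mx = eta_bg.max()
    log_z = mx + math.log(np.mean(np.exp(eta_bg - mx)))
    return float(np.mean(f_pres @ lam) - log_z - np.sum(betas * np.abs(lam)))


def fit_maxent(
    f_pres: np.ndarray,
    f_bg: np.ndarray,
    beta_multiplier: float = 1.0,
    max_iter: int = MAX_ITER,
    tol: float = DEFAULT_TOL,
    feature_map: FeatureMap | None = None,
) -> MaxentModel:
    """Coordinate-wise proximal Newton on the penalized Gibbs likelihood.

    One iteration is a full sweep over features; stops when the objective
    improves by less than ``tol`` or at ``max_iter`` sweeps.
    """
    m, J = f_pres.shape
    if m < 5:
        raise ValueError(f"need >= 5 presences, got {m}")
    if f_bg.shape[1] != J:
        raise ValueError("presence/background feature dimension mismatch")

    s = f_pres.std(axis=0)
    betas = beta_multiplier * np.maximum(s, _S_FLOOR) / math.sqrt(m)
    p_mean = f_pres.mean(axis=0)

    lam = np.zeros(J)
    eta = np.zeros(f_bg.shape[0])
    obj = penalized_objective(lam, f_pres, f_bg, betas)
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        mx = eta.max()
        w = np.exp(eta - mx)
        w /= w.sum()
        for j in range(J):
            fj = f_bg[:, j]
            ej = float(w @ fj)
            hj = float(w @ (fj * fj)) - ej * ej
            if hj < 1e-12:
                continue
            gj = p_mean[j] - ej
            z = lam[j] + gj / hj
            thr = betas[j] / hj
            new = math.copysign(max(abs(z) - thr, 0.0), z)
            d = new - lam[j]
            if d != 0.0:
                lam[j] = new
                eta += d * fj
                w = np.exp(eta - eta.max())
                w /= w.sum()
        new_obj = penalized_objective(lam, f_pres, f_bg, betas)
        if not math.isfinite(new_obj):
            raise RuntimeError("maxent objective diverged (NaN); last-good state lost")
        if abs(new_obj - obj) < tol:
            obj = new_obj
            converged = True
            break
        obj = new_obj

    eta_bg = f_bg @ lam
    mx = eta_bg.max()
    exp_eta = np.exp(eta_bg - mx)
    log_z_mean = mx + math.log(exp_eta.mean())
    z_sum = float(exp_eta.sum() * math.exp(mx))
    raw = exp_eta / exp_eta.sum()
    entropy = float(-(raw * np.log(np.maximum(raw, 1e-300))).sum())
    return MaxentModel(
        feature_map=feature_map, lam=lam, beta_multiplier=beta_multiplier,
        betas=betas, log_z_mean=log_z_mean, z_sum=z_sum, entropy=entropy,
        iterations=it, converged=converged, objective=obj,
    )


def predict_features(model: MaxentModel, features: np.ndarray, output: str = "raw") -> np.ndarray:
    """Raw (sums to 1 over the training background) or logistic suitability."""
    eta = features @ model.lam
    # work in log space: extrapolated cells can otherwise overflow exp
    raw = np.exp(np.clip(eta - math.log(model.z_sum), -745.0, 709.0))
    if output == "raw":
        return raw
    if output == "logistic":
        s = raw * math.exp(model.entropy)
        return s / (1.0 + s)
    raise ValueError(f"unknown output kind {output!r}")


def predict_table(model: MaxentModel, table: pd.DataFrame, output: str = "raw") -> np.ndarray:
    if model.feature_map is None:
        raise ValueError("model has no feature map; use predict_features")
    return predict_features(model, model.feature_map.transform(table), output)


# ---------------------------------------------------------------------------
# evaluation


def auc_score(pred_presence: np.ndarray, pred_background: np.ndarray) -> float:
    """Mann-Whitney AUC (tie-aware): P(presence score > background score)."""
    from scipy.stats import rankdata

    pres = np.asarray(pred_presence, dtype=float)
    bg = np.asarray(pred_background, dtype=float)
    ranks = rankdata(np.concatenate([pres, bg]))
    n1, n0 = len(pres), len(bg)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def max_sss_threshold(
    pred_presence: np.ndarray, pred_background: np.ndarray
) -> tuple[float, float, float]:
    """Threshold maximizing sensitivity + specificity (ties -> lowest).

    Presences scoring >= threshold are predicted suitable.  Returns
    (threshold, sensitivity, specificity).
    """
    pres = np.asarray(pred_presence, dtype=float)
    bg = np.asarray(pred_background, dtype=float)
    if pres.size == 0 or bg.size == 0:
        raise ValueError("both prediction sets must be non-empty")
    cands = np.unique(np.concatenate([pres, bg]))
    best = None
    for thr in cands:
        sens = float(np.mean(pres >= thr))
        spec = float(np.mean(bg < thr))
        key = (sens + spec, -thr)
        if best is None or key > best[0]:
            best = (key, thr, sens, spec)
    _, thr, sens, spec = best
    return float(thr), sens, spec


@dataclass
class EvalResult:
    feature_combo: str
    beta_multiplier: float
    auc: float
    tss: float
    sensitivity: float
    specificity: float
    threshold: float
    fold_aucs: list[float]
    fold_thresholds: list[float]


def _stratified_folds(n_pres: int, n_bg: int, k: int, seed: int):
    rng = np.random.default_rng(seed)
    def split(n):
        idx = rng.permutation(n)
        return [np.sort(idx[i::k]) for i in range(k)]
    return list(zip(split(n_pres), split(n_bg)))


def cross_validate(
    presence_table: pd.DataFrame,
    background_table: pd.DataFrame,
    combos: dict[str, tuple[str, ...]] | None = None,
    multipliers=BETA_MULTIPLIERS,
    k: int = 10,
    seed: int = 0,
    hinge_knots: int = 20,
    max_iter: int = MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> tuple[MaxentModel, EvalResult, list[EvalResult]]:
    """Grid of feature combos x multipliers under shared stratified folds.

    Best config = highest mean test AUC, ties by TSS, then by larger
    multiplier.  The returned model is the best config refit on all data;
    its reported threshold is the fold-average max_sss threshold.
    """
    if combos is None:
        combos = FEATURE_COMBOS
    n_pres, n_bg = len(presence_table), len(background_table)
    if n_pres < k:
        raise ValueError(f"need >= {k} presences for {k}-fold CV")
    folds = _stratified_folds(n_pres, n_bg, k, seed)

    results: list[EvalResult] = []
    for combo_name, classes in combos.items():
        spec = FeatureSpec(classes=tuple(classes), hinge_knots_per_var=hinge_knots)
        for mult in multipliers:
            fold_aucs, fold_thrs, fold_sens, fold_spec = [], [], [], []
            for pres_test, bg_test in folds:
                pres_tr = np.setdiff1d(np.arange(n_pres), pres_test)
                bg_tr = np.setdiff1d(np.arange(n_bg), bg_test)
                if len(pres_test) == 0:
                    continue
                tr_p = presence_table.iloc[pres_tr]
                tr_b = background_table.iloc[bg_tr]
                fm = FeatureMap.fit(pd.concat([tr_p, tr_b], ignore_index=True), spec)
                model = fit_maxent(
                    fm.transform(tr_p), fm.transform(tr_b), mult,
                    max_iter=max_iter, tol=tol, feature_map=fm,
                )
                pp = predict_table(model, presence_table.iloc[pres_test])
                pb = predict_table(model, background_table.iloc[bg_test])
                fold_aucs.append(auc_score(pp, pb))
                thr, sens, spc = max_sss_threshold(pp, pb)
                fold_thrs.append(thr)
                fold_sens.append(sens)
                fold_spec.append(spc)
            sens = float(np.mean(fold_sens))
            spc = float(np.mean(fold_spec))
            results.append(
                EvalResult(
                    feature_combo=combo_name, beta_multiplier=mult,
                    auc=float(np.mean(fold_aucs)), tss=sens + spc - 1.0,
                    sensitivity=sens, specificity=spc,
                    threshold=float(np.mean(fold_thrs)),
                    fold_aucs=fold_aucs, fold_thresholds=fold_thrs,
                )
            )
    best = max(results, key=lambda r: (r.auc, r.tss, r.beta_multiplier))
    spec = FeatureSpec(classes=FEATURE_COMBOS.get(best.feature_combo, combos[best.feature_combo]),
                       hinge_knots_per_var=hinge_knots)
    fm = FeatureMap.fit(pd.concat([presence_table, background_table], ignore_index=True), spec)
    model = fit_maxent(
        fm.transform(presence_table), fm.transform(background_table),
        best.beta_multiplier, max_iter=max_iter, tol=tol, feature_map=fm,
    )
    return model, best, results


def univariate_cv_auc(
    presence_table: pd.DataFrame,
    background_table: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
) -> dict[str, float]:
    """Cross-validated AUC of single-covariate models, for collinearity
    screening ("superior model performance" scores)."""
    scores: dict[str, float] = {}
    spec = FeatureSpec(classes=("linear", "quadratic"), hinge_knots_per_var=2)
    folds = _stratified_folds(len(presence_table), len(background_table), k, seed)
    for col in presence_table.columns:
        aucs = []
        for pres_test, bg_test in folds:
            pres_tr = np.setdiff1d(np.arange(len(presence_table)), pres_test)
            bg_tr = np.setdiff1d(np.arange(len(background_table)), bg_test)
            tr_p = presence_table.iloc[pres_tr][[col]]
            tr_b = background_table.iloc[bg_tr][[col]]
            fm = FeatureMap.fit(pd.concat([tr_p, tr_b], ignore_index=True), spec)
            try:
                model = fit_maxent(fm.transform(tr_p), fm.transform(tr_b), 1.0,
                                   max_iter=200, tol=1e-4, feature_map=fm)
            except ValueError:
                continue
            pp = predict_table(model, presence_table.iloc[pres_test][[col]])
            pb = predict_table(model, background_table.iloc[bg_test][[col]])
            aucs.append(auc_score(pp, pb))
        scores[col] = float(np.mean(aucs)) if aucs else 0.0
    return scores


# ---------------------------------------------------------------------------
# binary maps and area accounting


@dataclass
class AreaReport:
    total_suitable_km2: float
    by_habitat_class_km2: dict[int, float]
    unoccupied_suitable_km2: float
    occupied_buffer_radius_m: float

    def percent_of_total(self, km2: float) -> float:
        """Share of the total suitable area, in percent."""
        return percent_share(km2, self.total_suitable_km2)


def percent_share(part: float, total: float) -> float:
    if total <= 0:
        raise ValueError("total must be positive")
    return 100.0 * part / total


def binarize_and_account(
    suitability: Raster,
    threshold: float,
    habitat: Raster | None = None,
    mask_polygons: list[Polygon] | None = None,
    occupied_nests: np.ndarray | None = None,
    buffer_radius: float = BUFFER_RADIUS_M,
) -> tuple[Raster, AreaReport]:
    """Binary suitable/non-suitable map plus area totals.

    Cells inside ``mask_polygons`` (e.g. peripheral forest/pasture) are set
    unsuitable; ``unoccupied`` excludes cells within ``buffer_radius`` of any
    occupied nest.
    """
    if habitat is not None and not suitability.same_grid(habitat):
        raise ValueError("suitability and habitat rasters are on different grids")
    suitable = suitability.values >= threshold
    if suitability.nodata is not None:
        suitable &= suitability.values != suitability.nodata

    cx, cy = suitability.cell_centres()
    if mask_polygons:
        from .geo import points_in_polygon

        xs, ys = np.meshgrid(cx, cy)
        masked = np.zeros(suitable.shape, dtype=bool)
        for poly in mask_polygons:
            masked |= points_in_polygon(xs.ravel(), ys.ravel(), poly).reshape(suitable.shape)
        suitable &= ~masked

    cell_km2 = (suitability.cell_size / 1000.0) ** 2
    total = float(suitable.sum()) * cell_km2

    by_class: dict[int, float] = {}
    if habitat is not None:
        for code in np.unique(habitat.values):
            by_class[int(code)] = float((suitable & (habitat.values == code)).sum()) * cell_km2

    unoccupied = total
    if occupied_nests is not None and len(occupied_nests):
        xs, ys = np.meshgrid(cx, cy)
        occ = np.zeros(suitable.shape, dtype=bool)
        r2 = buffer_radius**2
        for nx, ny in np.asarray(occupied_nests, dtype=float).reshape(-1, 2):
            occ |= (xs - nx) ** 2 + (ys - ny) ** 2 <= r2
        unoccupied = float((suitable & ~occ).sum()) * cell_km2

    binary = Raster(
        suitability.origin, suitability.cell_size,
        suitable.astype(np.int64), nodata=None, kind="categorical",
    )
    return binary, AreaReport(total, by_class, unoccupied, buffer_radius)


def buffer_area_km2(
    radius_m: float = BUFFER_RADIUS_M, cell_m: float = 50.0
) -> float:
    """Area of one isolated nest buffer as counted on a grid of cell_m cells."""
    half = int(math.ceil(radius_m / cell_m)) + 2
    c = (np.arange(-half, half + 1) + 0.0) * cell_m
    xs, ys = np.meshgrid(c, c)
    inside = xs**2 + ys**2 <= radius_m**2
    return float(inside.sum()) * (cell_m / 1000.0) ** 2
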