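"""Random-intercept GLMMs and parametric-bootstrap likelihood-ratio tests.

Two model families cover the foraging-area regressions: a Poisson GLMM with
log link for occupancy span (in whole days) and a Gaussian linear mixed
model on log-transformed response and predictor for area.  The Gaussian
family is fit by exact profiled maximum likelihood; the Poisson family by
maximizing an adaptive Gauss-Hermite (Laplace at one node) approximation to
the marginal likelihood.  Significance of the slope comes from a parametric
bootstrap of the likelihood-ratio statistic under the fitted null model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

log = logging.getLogger(__name__)

N_BOOT = 1000
_LOG_S2U_MIN, _LOG_S2U_MAX = -12.0, 8.0


@dataclass
class GlmmFit:
    family: str  # "poisson" or "gaussian"
    beta: np.ndarray  # (intercept[, slope]) on the (transformed) scale
    sigma2_u: float
    sigma2_e: float | None  # gaussian only
    loglik: float
    cov_beta: np.ndarray
    log_response: bool
    log_predictor: bool
    has_slope: bool
    converged: bool = True
    singular: bool = False  # sigma2_u pinned at (numerical) zero
    # data retained for simulation/refitting
    y: np.ndarray = field(default=None, repr=False)
    x: np.ndarray = field(default=None, repr=False)
    groups: np.ndarray = field(default=None, repr=False)

    @property
    def fitted(self) -> np.ndarray:
        eta = self._design() @ self.beta
        return np.exp(eta) if self.family == "poisson" else eta

    def _design(self) -> np.ndarray:
        if self.has_slope:
            return np.column_stack([np.ones_like(self.x), self.x])
        return np.ones((len(self.y), 1))


@dataclass(frozen=True)
class LrtResult:
    statistic: float
    df: int
    p_boot: float
    n_boot: int
    n_dropped: int
    boot_statistics: np.ndarray = field(repr=False)


# ---------------------------------------------------------------------------
# Gaussian linear mixed model (exact profiled ML)


def _lmm_profile(psi: float, y: np.ndarray, X: np.ndarray, gi: np.ndarray, ng: np.ndarray):
    """Profiled ML pieces for variance ratio psi = sigma2_u / sigma2_e."""
    n, p = X.shape
    G = len(ng)
    shrink = psi / (1.0 + ng * psi)  # per group
    XtX = X.T @ X
    Xty = X.T @ y
    Sx = np.zeros((G, p))
    for j in range(p):
        Sx[:, j] = np.bincount(gi, weights=X[:, j], minlength=G)
    Sy = np.bincount(gi, weights=y, minlength=G)
    A = XtX - (Sx * shrink[:, None]).T @ Sx
    b = Xty - Sx.T @ (shrink * Sy)
    beta = np.linalg.solve(A, b)
    r = y - X @ beta
    Sr = np.bincount(gi, weights=r, minlength=G)
    rss = float(r @ r - shrink @ (Sr * Sr))
    sigma2_e = rss / n
    # floor only inside the log: interpolating fits (rss = 0) stay reportable
    loglik = -0.5 * (
        n * math.log(2 * math.pi * max(sigma2_e, 1e-300))
        + float(np.sum(np.log(1.0 + ng * psi))) + n
    )
    cov_beta = sigma2_e * np.linalg.inv(A)
    return loglik, beta, sigma2_e, cov_beta


def _fit_lmm(y: np.ndarray, X: np.ndarray, gi: np.ndarray) -> tuple:
    ng = np.bincount(gi).astype(float)

    def neg(log_psi):
        ll, *_ = _lmm_profile(math.exp(log_psi), y, X, gi, ng)
        return -ll

    res = optimize.minimize_scalar(neg, bounds=(-12.0, 8.0), method="bounded",
                                   options={"xatol": 1e-8})
    ll0, *_ = _lmm_profile(0.0, y, X, gi, ng)
    if -res.fun >= ll0:
        psi = math.exp(res.x)
        singular = res.x <= -11.0
    else:
        psi, singular = 0.0, True
    ll, beta, sigma2_e, cov_beta = _lmm_profile(psi, y, X, gi, ng)
    return beta, psi * sigma2_e, sigma2_e, ll, cov_beta, singular


# ---------------------------------------------------------------------------
# Poisson GLMM (adaptive Gauss-Hermite / Laplace marginal likelihood)


def _poisson_marginal_ll(
    beta: np.ndarray,
    log_s2u: float,
    ysum: np.ndarray,
    const: float,
    x_cols: np.ndarray,
    gi: np.ndarray,
    G: int,
    n_quad: int,
    gh_nodes: np.ndarray,
    gh_logw: np.ndarray,
    u_start: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Marginal loglik given fixed effects and log random-intercept variance.

    Inner Newton finds the conditional mode per group; with one quadrature
    node this is the Laplace approximation, otherwise adaptive GH centred
    and scaled at the mode.
    """
    s2u = math.exp(log_s2u)
    eta0 = x_cols @ beta
    s0 = np.bincount(gi, weights=np.exp(eta0), minlength=G)  # sum_i exp(eta0) per group

    u = np.zeros(G) if u_start is None else u_start.copy()
    for _ in range(60):
        mu = s0 * np.exp(u)
        grad = ysum - mu - u / s2u
        hess = mu + 1.0 / s2u
        step = grad / hess
        np.clip(step, -4.0, 4.0, out=step)
        u += step
        if np.max(np.abs(step)) < 1e-9:
            break

    mu = s0 * np.exp(u)
    neg_h2 = mu + 1.0 / s2u  # -h''(u_hat) per group

    if n_quad <= 1:
        h_mode = ysum * u - s0 * np.exp(u) - u * u / (2.0 * s2u)
        ll_groups = h_mode - 0.5 * np.log(s2u * neg_h2)
    else:
        sd = 1.0 / np.sqrt(neg_h2)
        uk = u[:, None] + math.sqrt(2.0) * sd[:, None] * gh_nodes[None, :]
        h_uk = (
            ysum[:, None] * uk
            - s0[:, None] * np.exp(uk)
            - uk * uk / (2.0 * s2u)
        )
        integrand = h_uk + gh_logw[None, :] + gh_nodes[None, :] ** 2
        lmax = integrand.max(axis=1)
        ll_groups = (
            lmax
            + np.log(np.sum(np.exp(integrand - lmax[:, None]), axis=1))
            + np.log(math.sqrt(2.0) * sd)
            - 0.5 * math.log(2 * math.pi * s2u)
        )
    # const carries the u-independent Poisson pieces: sum_i y_i eta0_i - log y_i!
    return float(ll_groups.sum()) + const, u


def _poisson_ll_full(beta, log_s2u, y, X, gi, G, n_quad, gh_nodes, gh_logw, u_start=None,
                     ysum=None, xty=None, gl_sum=None):
    if ysum is None:
        ysum = np.bincount(gi, weights=y, minlength=G)
    if xty is None:
        xty = X.T @ y
    if gl_sum is None:
        gl_sum = float(special.gammaln(y + 1.0).sum())
    const = float(xty @ beta) - gl_sum
    ll, u = _poisson_marginal_ll(
        beta, log_s2u, ysum, const, X, gi, G, n_quad, gh_nodes, gh_logw, u_start
    )
    return ll, u


def _poisson_glm_start(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Plain Poisson GLM via a few IRLS steps (starting values only)."""
    beta = np.zeros(X.shape[1])
    beta[0] = math.log(max(y.mean(), 0.1))
    for _ in range(25):
        eta = np.clip(X @ beta, -30, 30)
        mu = np.exp(eta)
        W = mu
        z = eta + (y - mu) / np.maximum(mu, 1e-10)
        XtW = X.T * W
        try:
            new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(new - beta)) < 1e-10:
            beta = new
            break
        beta = new
    return beta


def _fit_poisson_glmm(
    y: np.ndarray,
    X: np.ndarray,
    gi: np.ndarray,
    n_quad: int = 9,
    tol: float = 1e-8,
    x0: np.ndarray | None = None,
    compute_cov: bool = True,
    maxfev: int = 3000,
):
    G = int(gi.max()) + 1
    gh_nodes, gh_w = np.polynomial.hermite.hermgauss(max(n_quad, 1))
    gh_logw = np.log(gh_w)
    p = X.shape[1]
    state = {"u": None}
    ysum = np.bincount(gi, weights=y, minlength=G)
    xty = X.T @ y
    gl_sum = float(special.gammaln(y + 1.0).sum())

    def neg(params):
        beta, log_s2u = params[:p], float(np.clip(params[p], _LOG_S2U_MIN, _LOG_S2U_MAX))
        ll, u = _poisson_ll_full(beta, log_s2u, y, X, gi, G, n_quad, gh_nodes, gh_logw,
                                 u_start=state["u"], ysum=ysum, xty=xty, gl_sum=gl_sum)
        state["u"] = u
        return -ll if math.isfinite(ll) else 1e300

    if x0 is None:
        x0 = np.append(_poisson_glm_start(y, X), math.log(0.5))
    # explicit simplex: NM's default 5% steps are badly scaled for near-zero slopes
    steps = np.full(p + 1, 0.1)
    steps[p] = 0.4
    if p > 1:
        span = np.ptp(X[:, 1:], axis=0)
        steps[1:p] = 0.5 / np.maximum(span, 1e-9)
    simplex = np.vstack([x0] + [x0 + steps[i] * np.eye(p + 1)[i] for i in range(p + 1)])
    res = optimize.minimize(neg, x0, method="Nelder-Mead",
                            options={"xatol": max(1e-6, 10 * tol), "fatol": tol,
                                     "maxiter": maxfev, "maxfev": maxfev,
                                     "initial_simplex": simplex})
    beta = res.x[:p]
    log_s2u = float(np.clip(res.x[p], _LOG_S2U_MIN, _LOG_S2U_MAX))
    ll = -res.fun
    singular = log_s2u <= _LOG_S2U_MIN + 0.5

    # numerical covariance of beta from the full-parameter Hessian
    cov_beta = _numeric_cov(lambda th: -neg(th), res.x, p) if compute_cov else np.full((p, p), np.nan)
    return beta, math.exp(log_s2u), ll, cov_beta, bool(res.success), singular


def _numeric_cov(f, theta: np.ndarray, p: int) -> np.ndarray:
    k = len(theta)
    hess = np.zeros((k, k))
    eps = 1e-4 * np.maximum(np.abs(theta), 1.0)
    f0 = f(theta)
    for i in range(k):
        for j in range(i, k):
            ti = np.array(theta)
            if i == j:
                tp, tm = theta.copy(), theta.copy()
                tp[i] += eps[i]
                tm[i] -= eps[i]
                hess[i, i] = (f(tp) - 2 * f0 + f(tm)) / eps[i] ** 2
            else:
                tpp, tpm, tmp, tmm = (theta.copy() for _ in range(4))
                tpp[[i, j]] += [eps[i], eps[j]]
                tpm[i] += eps[i]; tpm[j] -= eps[j]
                tmp[i] -= eps[i]; tmp[j] += eps[j]
                tmm[[i, j]] -= [eps[i], eps[j]]
                hess[i, j] = hess[j, i] = (f(tpp) - f(tpm) - f(tmp) + f(tmm)) / (
                    4 * eps[i] * eps[j]
                )
    try:
        cov = np.linalg.inv(-hess)
        return cov[:p, :p]
    except np.linalg.LinAlgError:
        return np.full((p, p), np.nan)


# ---------------------------------------------------------------------------
# public API


def fit_glmm(
    table: pd.DataFrame,
    response: str,
    predictor: str | None,
    group: str,
    family: str = "poisson",
    log_response: bool | None = None,
    log_predictor: bool | None = None,
    n_quad: int = 9,
    tol: float = 1e-8,
) -> GlmmFit:
    """Fit a random-intercept GLMM; ``predictor=None`` gives the null model.

    Defaults follow the two foraging-area models: the Gaussian family logs
    both response and predictor (natural log); the Poisson family models the
    integer response on the untransformed predictor.
    """
    family = family.lower()
    if family not in ("poisson", "gaussian"):
        raise ValueError(f"unsupported family {family!r}")
    if log_response is None:
        log_response = family == "gaussian"
    if log_predictor is None:
        log_predictor = family == "gaussian"

    codes, _ = pd.factorize(table[group], sort=True)
    if codes.max() < 1:
        raise ValueError("need >= 2 individuals (groups)")
    gi = codes.astype(np.int64)

    y = table[response].to_numpy(dtype=float)
    has_slope = predictor is not None
    if has_slope:
        x = table[predictor].to_numpy(dtype=float)
        if log_predictor:
            if np.any(x <= 0):
                raise ValueError("log predictor transform requires positive values")
            x = np.log(x)
    else:
        x = np.zeros_like(y)

    if family == "gaussian":
        if log_response:
            if np.any(y <= 0):
                raise ValueError("log response transform requires positive values")
            yt = np.log(y)
        else:
            yt = y
        X = np.column_stack([np.ones_like(yt), x]) if has_slope else np.ones((len(yt), 1))
        beta, s2u, s2e, ll, cov_beta, singular = _fit_lmm(yt, X, gi)
        return GlmmFit(
            family, beta, s2u, s2e, ll, cov_beta, log_response, log_predictor,
            has_slope, singular=singular, y=yt, x=x, groups=gi,
        )

    yi = np.round(y).astype(float)
    if np.any(yi < 0):
        raise ValueError("Poisson response must be non-negative")
    X = np.column_stack([np.ones_like(yi), x]) if has_slope else np.ones((len(yi), 1))
    beta, s2u, ll, cov_beta, ok, singular = _fit_poisson_glmm(yi, X, gi, n_quad=n_quad, tol=tol)
    return GlmmFit(
        family, beta, s2u, None, ll, cov_beta, False, log_predictor,
        has_slope, converged=ok, singular=singular, y=yi, x=x, groups=gi,
    )


def simulate_from_fit(fit: GlmmFit, rng: np.random.Generator) -> np.ndarray:
    """Draw one replicate response vector from the fitted model."""
    G = int(fit.groups.max()) + 1
    u = rng.normal(0.0, math.sqrt(max(fit.sigma2_u, 0.0)), G)
    eta = fit._design() @ fit.beta + u[fit.groups]
    if fit.family == "poisson":
        return rng.poisson(np.exp(np.clip(eta, -30, 30))).astype(float)
    return eta + rng.normal(0.0, math.sqrt(fit.sigma2_e), len(eta))


def _refit(fit: GlmmFit, y_new: np.ndarray, has_slope: bool, n_quad: int, tol: float) -> float:
    gi = fit.groups
    x = fit.x
    X = np.column_stack([np.ones_like(y_new), x]) if has_slope else np.ones((len(y_new), 1))
    if fit.family == "gaussian":
        _, _, _, ll, _, _ = _fit_lmm(y_new, X, gi)
        return ll
    # warm start at the parent fit's estimates; slope starts at 0 when absent there
    if has_slope and len(fit.beta) == 2:
        x0 = np.array([fit.beta[0], fit.beta[1], math.log(max(fit.sigma2_u, 1e-4))])
    elif has_slope:
        x0 = np.array([fit.beta[0], 0.0, math.log(max(fit.sigma2_u, 1e-4))])
    else:
        x0 = np.array([fit.beta[0], math.log(max(fit.sigma2_u, 1e-4))])
    _, _, ll, _, _, _ = _fit_poisson_glmm(
        y_new, X, gi, n_quad=n_quad, tol=tol, x0=x0, compute_cov=False, maxfev=800
    )
    return ll


def bootstrap_lrt(
    null_fit: GlmmFit,
    alt_fit: GlmmFit,
    n_boot: int = N_BOOT,
    seed: int = 0,
    n_quad: int = 1,
    tol: float = 1e-5,
    max_dropped_frac: float = 0.10,
) -> LrtResult:
    """Parametric bootstrap of the LRT statistic under the fitted null.

    Replicates are simulated from ``null_fit`` (new random intercepts each
    time), both models refit, and p = (1 + #{T* >= T_obs}) / (n_boot + 1).
    Bootstrap refits use the Laplace approximation by default for speed.
    """
    if null_fit.has_slope or not alt_fit.has_slope:
        raise ValueError("null must be the slope-free submodel of alt")
    if null_fit.family != alt_fit.family:
        raise ValueError("families differ between null and alt")
    t_obs = 2.0 * (alt_fit.loglik - null_fit.loglik)
    if t_obs < -1e-6:
        log.warning("negative LRT statistic %.3g clipped to 0 (numerical)", t_obs)
    t_obs = max(t_obs, 0.0)

    stats_boot = []
    dropped = 0
    for b in range(n_boot):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(b,)))
        y_star = simulate_from_fit(null_fit, rng)
        try:
            ll0 = _refit(null_fit, y_star, has_slope=False, n_quad=n_quad, tol=tol)
            ll1 = _refit(alt_fit, y_star, has_slope=True, n_quad=n_quad, tol=tol)
            t = 2.0 * (ll1 - ll0)
            if not math.isfinite(t):
                raise FloatingPointError("non-finite statistic")
            stats_boot.append(max(t, 0.0))
        except (np.linalg.LinAlgError, FloatingPointError, ValueError) as exc:
            dropped += 1
            log.info("bootstrap replicate %d dropped: %s", b, exc)
    if dropped > max_dropped_frac * n_boot:
        raise RuntimeError(f"{dropped}/{n_boot} bootstrap replicates failed")
    stats_boot = np.array(stats_boot)
    n_eff = len(stats_boot)
    p = (1.0 + float(np.sum(stats_boot >= t_obs))) / (n_eff + 1.0)
    return LrtResult(t_obs, 1, p, n_eff, dropped, stats_boot)


def predict_with_pe(
    fit: GlmmFit,
    grid: np.ndarray,
    level: float = 0.6745,
    response_scale: bool = True,
) -> pd.DataFrame:
    """Population-level prediction curve with a symmetric normal interval.

    ``level`` = 0.6745 is the probable-error band expected to contain half
    of new values; the prediction variance combines fixed-effect uncertainty
    with the random-intercept variance.
    """
    if not fit.has_slope:
        raise ValueError("prediction curve needs a slope model")
    grid = np.asarray(grid, dtype=float)
    x = np.log(grid) if fit.log_predictor else grid
    X = np.column_stack([np.ones_like(x), x])
    eta = X @ fit.beta
    var = np.einsum("ij,jk,ik->i", X, fit.cov_beta, X) + max(fit.sigma2_u, 0.0)
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo, hi = eta - z * np.sqrt(var), eta + z * np.sqrt(var)
    if response_scale and (fit.family == "poisson" or fit.log_response):
        mean, lo, hi = np.exp(eta), np.exp(lo), np.exp(hi)
    else:
        mean = eta
    return pd.DataFrame({"predictor": grid, "mean": mean, "lower": lo, "upper": hi})
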