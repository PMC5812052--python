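"""Per-group negative-binomial smoothing splines for longitudinal counts.

Model: the count of subject i of group k at time t is

    Y_tki ~ NB(alpha, p(t, k)),   eta(t, k) = logit p(t, k),

with shape alpha > 0 shared within a group and eta(., k) a smooth function of
time.  The group mean trajectory is mu(t) = alpha * (1 - p) / p =
alpha * exp(-eta(t)), i.e. a log-link NB regression with variance
mu + mu^2 / alpha.  The curve is estimated by penalized maximum likelihood,

    min_{eta, alpha}  -loglik + lambda * J(eta),   J(eta) = int eta''(t)^2 dt,

over the cubic-spline space with knots at the group's distinct observed
times; lambda is chosen by cross-validation on held-out NB log-likelihood and
alpha by profile likelihood.  The log-likelihood uses the gamma-function form
of the NB mass so fractional (normalized) counts are admissible.

A LOWESS backend with the same curve interface is provided so the interval
test is smoother-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.special import gammaln, digamma, polygamma
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .core_data import FeatureSeries

__all__ = [
    "FitError", "SmootherConfig", "NBSplineFit", "LowessFit",
    "nb_loglik", "fit_nb_spline", "fit_lowess", "fit_group_curve",
    "predict_mean_curve",
]

_ALPHA_MIN, _ALPHA_MAX = 1e-3, 1e6
_ETA_CLIP = 30.0


class FitError(ValueError):
    """Raised when a group's curve cannot be fitted (feature untestable)."""


@dataclass
class SmootherConfig:
    """Smoother choice and tuning knobs shared by both backends.

    lambda_grid is a relative grid; it is rescaled per fit so that the
    penalty and the data term are commensurate (see ``_lambda_scale``).
    ``fixed_lambda`` (relative units) bypasses cross-validation — used for
    permutation refits, which reuse the lambda selected on the observed data.
    """

    smoother: str = "nb_spline"
    lambda_grid: np.ndarray = field(
        default_factory=lambda: np.logspace(-4, 4, 10))
    cv_folds: int = 5
    cv: str = "kfold"                 # "kfold" over samples or "loso"
    lowess_span: float = 0.67
    share_alpha: bool = False
    fixed_lambda: float | None = None
    max_iter: int = 200
    tol: float = 1e-8
    curve_floor: float = 1e-6

    def __post_init__(self) -> None:
        self.lambda_grid = np.asarray(self.lambda_grid, dtype=float)
        if self.lambda_grid.size == 0 or np.any(self.lambda_grid <= 0):
            raise ValueError("lambda_grid must be non-empty and positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0 < self.lowess_span <= 1:
            raise ValueError("lowess_span must be in (0, 1]")
        if self.smoother not in ("nb_spline", "lowess"):
            raise ValueError(f"unknown smoother {self.smoother!r}")


# ---------------------------------------------------------------------------
# B-spline basis with curvature penalty, cached by the distinct-times vector.
# ---------------------------------------------------------------------------

class _Basis:
    """Cubic B-spline basis on distinct times tau_1 < ... < tau_K.

    Holds the design matrix at the knots and the roughness penalty
    Omega_ij = int B_i'' B_j'' dt (exact via 2-point Gauss-Legendre, the
    integrand being piecewise quadratic).
    """

    def __init__(self, tau: np.ndarray):
        tau = np.asarray(tau, dtype=float)
        if len(tau) < 3:
            raise FitError("need at least 3 distinct time points")
        k = 3
        knots = np.r_[[tau[0]] * (k + 1), tau[1:-1], [tau[-1]] * (k + 1)]
        nb = len(knots) - k - 1
        self.tau = tau
        self.knots = knots
        self.nbasis = nb
        spl = BSpline(knots, np.eye(nb), k, extrapolate=False)
        self.B = spl(tau)                       # (K, nb)
        d2 = spl.derivative(2)
        # Gauss-Legendre(2) nodes per inter-knot interval
        a, b = tau[:-1], tau[1:]
        h = b - a
        off = h * (0.5 / np.sqrt(3.0))
        mid = 0.5 * (a + b)
        x = np.r_[mid - off, mid + off]
        w = np.r_[h, h] * 0.5
        D = d2(x)
        D[~np.isfinite(D)] = 0.0
        self.omega = (D * w[:, None]).T @ D
        self.omega = 0.5 * (self.omega + self.omega.T)
        self.lambda_scale = float(
            np.trace(self.B.T @ self.B) / max(np.trace(self.omega), 1e-12))

    def eval(self, times: np.ndarray) -> np.ndarray:
        spl = BSpline(self.knots, np.eye(self.nbasis), 3, extrapolate=False)
        return spl(times)


_BASIS_CACHE: dict[bytes, _Basis] = {}


def _get_basis(tau: np.ndarray) -> _Basis:
    key = np.ascontiguousarray(tau, dtype=float).tobytes()
    basis = _BASIS_CACHE.get(key)
    if basis is None:
        if len(_BASIS_CACHE) > 4096:
            _BASIS_CACHE.clear()
        basis = _Basis(tau)
        _BASIS_CACHE[key] = basis
    return basis


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def nb_loglik(counts, alpha: float, p) -> float:
    """NB log-likelihood of independent observations, gamma-function form.

    log P(Y=y) = lgamma(y+a) - lgamma(a) - lgamma(y+1) + a*log p + y*log(1-p);
    valid for real y >= 0, so normalized fractional counts are admissible.
    An empty observation set has log-likelihood 0.
    """
    y = np.asarray(counts, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.size == 0:
        return 0.0
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("success probabilities must lie strictly in (0, 1)")
    ll = (gammaln(y + alpha) - gammaln(alpha) - gammaln(y + 1.0)
          + alpha * np.log(p) + y * np.log1p(-p))
    return float(np.sum(ll))


def _alpha_moments(y: np.ndarray) -> float:
    m = float(np.mean(y))
    v = float(np.var(y))
    if v > m > 0:
        a = m * m / (v - m)
    else:
        a = 100.0
    return float(np.clip(a, 0.05, 1e4))


def _alpha_profile_update(y: np.ndarray, mu: np.ndarray, alpha: float,
                          n_steps: int = 6) -> float:
    """Newton steps in log(alpha) on the NB profile likelihood at fixed mu.

    With the mean curve held fixed the dispersion is well identified, so the
    curve/dispersion alternation does not crawl along a likelihood ridge.
    """
    n = len(y)
    a = alpha
    for _ in range(n_steps):
        am = a + mu
        g = (float(np.sum(digamma(y + a))) - n * digamma(a)
             + n * (1.0 + np.log(a))
             - float(np.sum(np.log(am))) - float(np.sum((y + a) / am)))
        h = (float(np.sum(polygamma(1, y + a))) - n * polygamma(1, a)
             + n / a - 2.0 * float(np.sum(1.0 / am))
             + float(np.sum((y + a) / (am * am))))
        # in u = log a: dl/du = a*g ; d2l/du2 = a*g + a^2*h
        du_grad = a * g
        du_hess = a * g + a * a * h
        if du_hess >= -1e-12:
            step = np.sign(du_grad) * 1.0
        else:
            step = -du_grad / du_hess
        step = float(np.clip(step, -2.0, 2.0))
        a_new = float(np.clip(a * np.exp(step), _ALPHA_MIN, _ALPHA_MAX))
        if abs(np.log(a_new / a)) < 1e-9:
            a = a_new
            break
        a = a_new
    return a


# ---------------------------------------------------------------------------
# Penalized IRLS at fixed alpha and lambda
# ---------------------------------------------------------------------------

_THETA_CLIP = 20.0


def _pirls(y: np.ndarray, idx: np.ndarray, basis: _Basis, alpha: float,
           lam_eff: float, coef0: np.ndarray | None, max_iter: int,
           tol: float) -> tuple[np.ndarray, float, bool]:
    """Penalized Fisher scoring for the log-mean curve theta = B @ coef.

    theta(t) = log mu(t); since eta = log alpha - theta, the curvature
    penalty on eta equals the one on theta, so this parameterization is the
    same model with the dispersion decoupled from the curve.  `idx` maps
    each observation to its row in the distinct-time design matrix, so
    per-iteration algebra is O(K^2) regardless of sample size.
    Returns (coef, penalized objective, converged).
    """
    B = basis.B
    nb = basis.nbasis
    K = len(basis.tau)
    pen = lam_eff * basis.omega + 1e-10 * np.eye(nb)
    const = float(np.sum(gammaln(y + alpha) - gammaln(alpha) - gammaln(y + 1.0)
                         )) + len(y) * alpha * np.log(alpha)

    if coef0 is None:
        theta0 = float(np.log(max(np.mean(y), 1e-3)))
        coef, *_ = np.linalg.lstsq(B, np.full(K, theta0), rcond=None)
    else:
        coef = coef0.copy()

    def objective(theta_obs: np.ndarray, c: np.ndarray) -> float:
        mu = np.exp(theta_obs)
        ll = const + float(np.sum(y * theta_obs
                                  - (y + alpha) * np.log(alpha + mu)))
        return -ll + lam_eff * float(c @ basis.omega @ c)

    theta = np.clip((B @ coef)[idx], -_THETA_CLIP, _THETA_CLIP)
    obj = objective(theta, coef)
    converged = False
    for _ in range(max_iter):
        mu = np.exp(theta)
        denom = 1.0 + mu / alpha
        w = mu / denom + 1e-10
        z = theta + (y - mu) / (mu + 1e-10)
        w_agg = np.bincount(idx, weights=w, minlength=K)
        wz_agg = np.bincount(idx, weights=w * z, minlength=K)
        A = (B.T * w_agg) @ B + pen
        b = B.T @ wz_agg
        try:
            coef_new = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            coef_new = np.linalg.lstsq(A, b, rcond=None)[0]
        # step halving keeps the penalized objective monotone
        step = 1.0
        for _half in range(6):
            c_try = coef + step * (coef_new - coef)
            theta_try = np.clip((B @ c_try)[idx], -_THETA_CLIP, _THETA_CLIP)
            obj_try = objective(theta_try, c_try)
            if obj_try <= obj + 1e-12:
                break
            step *= 0.5
        else:
            converged = True
            break
        rel = abs(obj - obj_try) / (abs(obj) + 1.0)
        coef, obj, theta = c_try, obj_try, theta_try
        if rel < tol:
            converged = True
            break
    return coef, obj, converged


@dataclass
class NBSplineFit:
    """A fitted per-group NB smoothing spline.

    ``coefficients`` parameterize the log-mean curve theta(t) = log mu(t);
    the success probability is p(t) = alpha / (alpha + mu(t)) and the logit
    curve is eta(t) = log alpha - theta(t), whose roughness equals theta's.
    """

    group: str
    alpha: float
    basis_knots: np.ndarray          # distinct observed times of the group
    coefficients: np.ndarray
    lambda_rel: float                # position on the relative grid
    lambda_eff: float                # lambda actually used in the objective
    time_range: tuple[float, float]
    converged: bool
    objective: float                 # penalized objective at the solution
    n_obs: int

    def _theta(self, times: np.ndarray) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        lo, hi = self.time_range
        if np.any(t < lo - 1e-9) or np.any(t > hi + 1e-9):
            raise ValueError(
                f"prediction times outside fitted range [{lo}, {hi}]")
        t = np.clip(t, lo, hi)
        basis = _get_basis(self.basis_knots)
        spl = BSpline(basis.knots, self.coefficients, 3, extrapolate=False)
        theta = spl(t)
        theta[~np.isfinite(theta)] = 0.0  # guard boundary rounding
        return np.clip(theta, -_THETA_CLIP, _THETA_CLIP)

    def predict_mean(self, times) -> np.ndarray:
        """Mean abundance mu(t); strictly positive and smooth in t."""
        return np.exp(self._theta(np.atleast_1d(times)))

    def predict_p(self, times) -> np.ndarray:
        """NB success probability p(t) = alpha / (alpha + mu(t)) in (0,1)."""
        mu = self.predict_mean(times)
        return self.alpha / (self.alpha + mu)

    def predict_eta(self, times) -> np.ndarray:
        """Logit curve eta(t) = log(p / (1-p)) = log alpha - log mu(t)."""
        return np.log(self.alpha) - self._theta(np.atleast_1d(times))

    def roughness(self) -> float:
        """J(eta) = int eta''(t)^2 dt of the fitted curve."""
        basis = _get_basis(self.basis_knots)
        return float(self.coefficients @ basis.omega @ self.coefficients)


@dataclass
class LowessFit:
    """Locally weighted regression curve with the NBSplineFit interface."""

    group: str
    times: np.ndarray                # unique sorted observed times
    values: np.ndarray               # fitted (floored) means at those times
    time_range: tuple[float, float]
    converged: bool = True
    alpha: float = float("nan")

    def predict_mean(self, times) -> np.ndarray:
        t = np.atleast_1d(np.asarray(times, dtype=float))
        lo, hi = self.time_range
        if np.any(t < lo - 1e-9) or np.any(t > hi + 1e-9):
            raise ValueError(
                f"prediction times outside fitted range [{lo}, {hi}]")
        return np.interp(np.clip(t, lo, hi), self.times, self.values)


def _group_arrays(series: FeatureSeries, group: str) -> tuple[np.ndarray, np.ndarray]:
    mask = series.group_mask(group)
    if not mask.any():
        raise FitError(f"no observations in group {group!r}")
    return series.times[mask], series.counts[mask]


def _check_fit_preconditions(t: np.ndarray, y: np.ndarray, group: str) -> None:
    if len(y) < 4:
        raise FitError(
            f"group {group!r}: need >= 4 observations, have {len(y)}")
    if len(np.unique(t)) < 3:
        raise FitError(
            f"group {group!r}: need >= 3 distinct time points")
    if not np.any(y > 0):
        raise FitError(
            f"group {group!r}: all counts are zero; curve is degenerate")


def _fit_fixed_lambda(t: np.ndarray, y: np.ndarray, lam_rel: float,
                      config: SmootherConfig, alpha_fixed: float | None = None,
                      ) -> tuple[np.ndarray, float, float, float, bool]:
    """Alternate PIRLS over coefficients with profile updates of alpha."""
    tau, idx = np.unique(t, return_inverse=True)
    basis = _get_basis(tau)
    # scale so the relative grid brackets the under/over-smoothing regimes
    # for any sample size and time spacing
    lam_eff = lam_rel * len(y) * basis.lambda_scale
    alpha = alpha_fixed if alpha_fixed is not None else _alpha_moments(y)
    coef = None
    obj_prev = np.inf
    converged = False
    obj = np.inf
    for _outer in range(25):
        coef, obj, conv = _pirls(y, idx, basis, alpha, lam_eff, coef,
                                 config.max_iter, config.tol)
        if alpha_fixed is None:
            theta = np.clip((basis.B @ coef)[idx], -_THETA_CLIP, _THETA_CLIP)
            alpha_new = _alpha_profile_update(y, np.exp(theta), alpha)
            moved = abs(np.log(alpha_new / alpha))
            alpha = alpha_new
        else:
            moved = 0.0
        rel = abs(obj_prev - obj) / (abs(obj) + 1.0)
        if moved < 1e-6 and rel < max(config.tol, 1e-8):
            converged = conv
            break
        obj_prev = obj
    return coef, alpha, lam_eff, obj, converged


def _cv_folds(t: np.ndarray, subjects: np.ndarray | None,
              config: SmootherConfig) -> list[np.ndarray]:
    """Cross-validation folds that keep each subject's samples together.

    Samples of one subject are serially correlated, so splitting them across
    folds leaks information and drives lambda toward interpolation; folds
    are therefore blocks of whole subjects ("loso" = one subject per fold).
    Fold assignment is deterministic (subjects in sorted order, round-robin).
    """
    n = len(t)
    if subjects is None:
        order = np.argsort(t, kind="stable")
        fold_of = np.empty(n, dtype=int)
        fold_of[order] = np.arange(n) % config.cv_folds
        return [fold_of == k for k in range(config.cv_folds)]
    levels = sorted(set(subjects.tolist()))
    if config.cv == "loso":
        return [np.asarray([s == lev for s in subjects]) for lev in levels]
    n_folds = min(config.cv_folds, len(levels))
    fold_of_subj = {lev: i % n_folds for i, lev in enumerate(levels)}
    fold_of = np.asarray([fold_of_subj[s] for s in subjects])
    return [fold_of == k for k in range(n_folds)]


def _select_lambda(t: np.ndarray, y: np.ndarray, subjects: np.ndarray | None,
                   config: SmootherConfig) -> float:
    """Pick lambda from the grid by held-out NB log-likelihood."""
    grid = config.lambda_grid
    if grid.size == 1:
        return float(grid[0])
    folds = _cv_folds(t, subjects, config)
    scores = np.full(grid.size, -np.inf)
    for gi, lam in enumerate(grid):
        total = 0.0
        used = 0
        for test_mask in folds:
            tr = ~test_mask
            t_tr, y_tr = t[tr], y[tr]
            if len(y_tr) < 4 or len(np.unique(t_tr)) < 3 or not np.any(y_tr > 0):
                continue
            try:
                coef, alpha, _, _, _ = _fit_fixed_lambda(t_tr, y_tr, lam, config)
            except (FitError, np.linalg.LinAlgError):
                continue
            tau = np.unique(t_tr)
            basis = _get_basis(tau)
            t_te = np.clip(t[test_mask], tau[0], tau[-1])
            spl = BSpline(basis.knots, coef, 3, extrapolate=False)
            theta_te = spl(t_te)
            theta_te[~np.isfinite(theta_te)] = 0.0
            mu_te = np.exp(np.clip(theta_te, -_THETA_CLIP, _THETA_CLIP))
            p_te = np.clip(alpha / (alpha + mu_te), 1e-12, 1 - 1e-12)
            total += nb_loglik(y[test_mask], alpha, p_te)
            used += 1
        if used:
            scores[gi] = total
    if not np.any(np.isfinite(scores)):
        return float(grid[grid.size // 2])
    best = np.max(scores)
    # among near-ties prefer the smoothest curve (largest lambda)
    ok = np.flatnonzero(scores >= best - 1e-9 * (abs(best) + 1.0))
    return float(grid[ok[-1]])


def fit_nb_spline(series: FeatureSeries, group: str,
                  config: SmootherConfig | None = None,
                  alpha_fixed: float | None = None) -> NBSplineFit:
    """Fit the penalized NB smoothing spline to one group's observations.

    lambda comes from cross-validation unless ``config.fixed_lambda`` is set
    (permutation refits reuse the observed fit's lambda).  alpha is profiled
    unless ``alpha_fixed`` pins it (used when pooling alpha across groups).
    Initialization is deterministic, so the fit involves no randomness.
    """
    config = config or SmootherConfig()
    t, y = _group_arrays(series, group)
    _check_fit_preconditions(t, y, group)
    subjects = series.subjects[series.group_mask(group)]
    if config.fixed_lambda is not None:
        lam_rel = float(config.fixed_lambda)
    else:
        lam_rel = _select_lambda(t, y, subjects, config)
    coef, alpha, lam_eff, obj, converged = _fit_fixed_lambda(
        t, y, lam_rel, config, alpha_fixed=alpha_fixed)
    tau = np.unique(t)
    return NBSplineFit(
        group=group, alpha=alpha, basis_knots=tau, coefficients=coef,
        lambda_rel=lam_rel, lambda_eff=lam_eff,
        time_range=(float(tau[0]), float(tau[-1])), converged=converged,
        objective=obj, n_obs=len(y))


def fit_lowess(series: FeatureSeries, group: str,
               config: SmootherConfig | None = None) -> LowessFit:
    """LOWESS curve through one group's counts, floored at a small positive
    value so areas under the curve are well-defined."""
    config = config or SmootherConfig(smoother="lowess")
    t, y = _group_arrays(series, group)
    _check_fit_preconditions(t, y, group)
    out = _sm_lowess(y, t, frac=config.lowess_span, return_sorted=True)
    tu, first = np.unique(out[:, 0], return_index=True)
    vals = np.maximum(out[first, 1], config.curve_floor)
    if not np.all(np.isfinite(vals)):
        raise FitError(f"group {group!r}: LOWESS produced non-finite values")
    return LowessFit(group=group, times=tu, values=vals,
                     time_range=(float(tu[0]), float(tu[-1])))


def fit_group_curve(series: FeatureSeries, group: str,
                    config: SmootherConfig | None = None,
                    alpha_fixed: float | None = None):
    """Dispatch to the configured smoother backend."""
    config = config or SmootherConfig()
    if config.smoother == "lowess":
        return fit_lowess(series, group, config)
    return fit_nb_spline(series, group, config, alpha_fixed=alpha_fixed)


def predict_mean_curve(fit, times) -> np.ndarray:
    """Evaluate a fitted curve's mean at the given times (no extrapolation)."""
    return fit.predict_mean(times)


def export_curve(fit, path: str, n_points: int = 101) -> None:
    """Write the fitted mean curve as a two-column TSV (time, mean)."""
    lo, hi = fit.time_range
    times = np.linspace(lo, hi, n_points)
    means = fit.predict_mean(times)
    with open(path, "w") as fh:
        fh.write("time\tmean\n")
        for t, m in zip(times, means):
            fh.write(f"{t:.10g}\t{m:.10g}\n")
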