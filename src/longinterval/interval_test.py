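"""Per-unit-interval area-ratio testing with a permutation null.

After the two phenotypic groups' abundance curves are fitted, each unit
interval [t, t+1] of the testing grid gets the signed, max-normalized area
difference

    AR = (A_g1 - A_g2) / max(A_g1, A_g2)  in  [-1, 1],

where A_gk is the area under group k's fitted curve on the interval.  The
null distribution of AR is built by permuting the subject-to-group
assignment (all of a subject's samples move together, preserving
within-subject correlation), refitting both curves and recomputing AR.
Per-interval p-values are two-sided on |AR| with an add-one correction, then
Benjamini-Hochberg adjusted (per feature by default).  Significant intervals
are only reported inside the overlap range — the time span in which both
groups actually have samples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from statsmodels.stats.multitest import multipletests

from .core_data import FeatureSeries, SampleMetadata
from .nb_spline import (
    FitError, LowessFit, NBSplineFit, SmootherConfig, fit_group_curve,
)

__all__ = [
    "TimeGrid", "IntervalResult", "FeatureTestResult", "TestConfig",
    "build_time_grid", "area_under_curve", "interval_areas", "area_ratio",
    "permutation_null", "interval_pvalues", "adjust_bh", "run_feature_test",
    "apply_global_adjustment",
]


@dataclass
class TimeGrid:
    """Strictly increasing grid points defining the tested unit intervals.

    All points lie inside the overlap range, the span where samples from
    both study groups are available.
    """

    points: np.ndarray
    overlap_range: tuple[float, float]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if len(self.points) < 2:
            raise ValueError("grid needs at least 2 points")
        if np.any(np.diff(self.points) <= 0):
            raise ValueError("grid points must be strictly increasing")
        lo, hi = self.overlap_range
        if self.points[0] < lo - 1e-9 or self.points[-1] > hi + 1e-9:
            raise ValueError("grid points fall outside the overlap range")

    @property
    def n_intervals(self) -> int:
        return len(self.points) - 1

    @property
    def intervals(self) -> list[tuple[float, float]]:
        return list(zip(self.points[:-1].tolist(), self.points[1:].tolist()))


@dataclass
class TestConfig:
    """Permutation-test settings."""

    __test__ = False  # not a pytest class, despite the name

    n_permutations: int = 1000
    p_threshold: float = 0.05
    adjust_method: str = "bh"
    adjust_scope: str = "per_feature"     # or "global"
    rng_seed: int = 0
    permute_subjects: bool = True         # False: permute sample labels
    pool_null: bool = False               # pool null draws across intervals
    max_failure_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.adjust_scope not in ("per_feature", "global"):
            raise ValueError("adjust_scope must be 'per_feature' or 'global'")


@dataclass
class IntervalResult:
    """Outcome of the test on one unit time interval of one feature."""

    feature_id: str
    start: float
    end: float
    area_group1: float
    area_group2: float
    ar: float
    pvalue: float
    adjusted_pvalue: float
    dominant_group: str | None
    significant: bool
    testable: bool


@dataclass
class FeatureTestResult:
    """All interval results of one feature plus merged significant spans."""

    feature_id: str
    group_levels: tuple[str, str]
    intervals: list[IntervalResult]
    merged: list[tuple[float, float, str]]
    untestable_reason: str | None = None
    n_failed_permutations: int = 0
    lambdas: tuple[float, float] | None = None

    @property
    def testable(self) -> bool:
        return self.untestable_reason is None


def build_time_grid(meta: list[SampleMetadata],
                    n_points: int | None = None) -> TimeGrid:
    """Unit-interval grid over the span where both groups have samples.

    The overlap range runs from the latest first-sample time to the earliest
    last-sample time across the two groups.  With integer times (and no
    explicit n_points) the grid has unit spacing; otherwise 20 equally
    spaced points are used.
    """
    groups = sorted({m.group for m in meta})
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, found {groups}")
    spans = {}
    for g in groups:
        times = [m.time for m in meta if m.group == g]
        if len(set(times)) < 2:
            raise ValueError(f"group {g!r} needs >= 2 distinct times")
        spans[g] = (min(times), max(times))
    lo = max(s[0] for s in spans.values())
    hi = min(s[1] for s in spans.values())
    if hi <= lo:
        raise ValueError(
            f"groups do not overlap in time (spans {spans}); "
            "no interval can be tested")
    if n_points is not None:
        if n_points < 2:
            raise ValueError("n_points must be >= 2")
        points = np.linspace(lo, hi, n_points)
    else:
        all_times = [m.time for m in meta]
        if all(float(t).is_integer() for t in all_times):
            points = np.arange(np.ceil(lo - 1e-9), np.floor(hi + 1e-9) + 1.0) + 0.0
            if len(points) < 2:
                points = np.linspace(lo, hi, 2)
        else:
            points = np.linspace(lo, hi, 20)
    return TimeGrid(points=points, overlap_range=(float(lo), float(hi)))


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(7)


def _curve_values(fit, times: np.ndarray, clamp: bool) -> np.ndarray:
    if clamp:
        lo, hi = fit.time_range
        times = np.clip(times, lo, hi)
    return fit.predict_mean(times)


def area_under_curve(fit, t0: float, t1: float, clamp: bool = False) -> float:
    """Area under the fitted mean curve over [t0, t1].

    Smooth spline curves use 7-point Gauss-Legendre quadrature; piecewise
    linear LOWESS curves are integrated exactly.  With ``clamp`` the curve is
    extended as a constant beyond its fitted time range (used during
    permutation refits whose groups may span less than the grid).
    """
    if t1 <= t0:
        raise ValueError("need t0 < t1")
    if not clamp:
        lo, hi = fit.time_range
        if t0 < lo - 1e-9 or t1 > hi + 1e-9:
            raise ValueError(
                f"interval [{t0}, {t1}] outside fitted range [{lo}, {hi}]")
    if isinstance(fit, LowessFit):
        breaks = fit.times[(fit.times > t0) & (fit.times < t1)]
        xs = np.r_[t0, breaks, t1]
        return float(np.trapezoid(_curve_values(fit, xs, True), xs))
    half = 0.5 * (t1 - t0)
    xs = 0.5 * (t0 + t1) + half * _GL_NODES
    vals = _curve_values(fit, xs, clamp)
    return float(half * np.dot(_GL_WEIGHTS, vals))


def interval_areas(fit, grid: TimeGrid, clamp: bool = False) -> np.ndarray:
    """Vector of areas under `fit` over each grid interval."""
    t0 = grid.points[:-1]
    t1 = grid.points[1:]
    if isinstance(fit, LowessFit):
        return np.asarray([
            area_under_curve(fit, a, b, clamp=True) for a, b in zip(t0, t1)])
    if not clamp:
        lo, hi = fit.time_range
        if t0[0] < lo - 1e-9 or t1[-1] > hi + 1e-9:
            raise ValueError("grid extends outside the fitted time range")
    half = 0.5 * (t1 - t0)
    xs = 0.5 * (t0 + t1)[:, None] + half[:, None] * _GL_NODES[None, :]
    vals = _curve_values(fit, xs.ravel(), True).reshape(xs.shape)
    return half * (vals @ _GL_WEIGHTS)


def area_ratio(a1: float, a2: float) -> float:
    """Signed max-normalized area difference in [-1, 1].

    Positive means group 1 is more abundant on the interval.  When both
    areas are zero the interval is untestable and NaN is returned (the
    caller marks it, no exception is raised).
    """
    if a1 < 0 or a2 < 0:
        raise ValueError("areas must be non-negative")
    m = max(a1, a2)
    if m == 0:
        return float("nan")
    return (a1 - a2) / m


def _observed_ar(series: FeatureSeries, grid: TimeGrid,
                 smoother: SmootherConfig, levels: tuple[str, str]):
    fit1 = fit_group_curve(series, levels[0], smoother)
    fit2 = fit_group_curve(series, levels[1], smoother)
    a1 = interval_areas(fit1, grid)
    a2 = interval_areas(fit2, grid)
    ar = np.asarray([area_ratio(x, y) for x, y in zip(a1, a2)])
    return fit1, fit2, a1, a2, ar


def _permuted_series(series: FeatureSeries, rng: np.random.Generator,
                     levels: tuple[str, str],
                     permute_subjects: bool) -> FeatureSeries:
    if permute_subjects:
        subjects = sorted(set(series.subjects.tolist()))
        current = {}
        for s, g in zip(series.subjects, series.groups):
            current[s] = g
        labels = np.asarray([current[s] for s in subjects], dtype=object)
        shuffled = labels[rng.permutation(len(labels))]
        new_of = dict(zip(subjects, shuffled))
        new_groups = np.asarray([new_of[s] for s in series.subjects],
                                dtype=object)
    else:
        new_groups = series.groups[rng.permutation(len(series.groups))]
    return FeatureSeries(series.feature_id, series.times, new_groups,
                         series.subjects, series.counts)


def permutation_null(series: FeatureSeries, grid: TimeGrid,
                     config: TestConfig, smoother: SmootherConfig,
                     lambdas: tuple[float, float] | None = None,
                     ) -> tuple[np.ndarray, int]:
    """Null AR draws per interval from group-label permutations.

    Subject-to-group labels are shuffled preserving group sizes, both curves
    are refitted (reusing `lambdas`, the smoothing parameters selected on the
    observed data, when given) and AR is recomputed on every interval.
    Permutations whose refit fails are discarded; if more than
    ``config.max_failure_fraction`` fail the feature is untestable.

    Returns (matrix of shape n_valid x n_intervals, number of failures).
    """
    rng = np.random.default_rng(config.rng_seed)
    levels = tuple(series.group_levels)
    if len(levels) != 2:
        raise FitError(f"need exactly two groups, found {levels}")
    cfg1 = smoother if lambdas is None else replace(
        smoother, fixed_lambda=lambdas[0])
    cfg2 = smoother if lambdas is None else replace(
        smoother, fixed_lambda=lambdas[1])
    draws = []
    failures = 0
    for _ in range(config.n_permutations):
        perm = _permuted_series(series, rng, levels, config.permute_subjects)
        try:
            f1 = fit_group_curve(perm, levels[0], cfg1)
            f2 = fit_group_curve(perm, levels[1], cfg2)
            a1 = interval_areas(f1, grid, clamp=True)
            a2 = interval_areas(f2, grid, clamp=True)
        except (FitError, np.linalg.LinAlgError):
            failures += 1
            continue
        draws.append([area_ratio(x, y) for x, y in zip(a1, a2)])
    if failures > config.max_failure_fraction * config.n_permutations:
        raise FitError(
            f"{failures}/{config.n_permutations} permutation refits failed")
    null = np.asarray(draws, dtype=float).reshape(len(draws), grid.n_intervals)
    return null, failures


def interval_pvalues(observed: np.ndarray, null: np.ndarray,
                     pool: bool = False) -> np.ndarray:
    """Two-sided permutation p-values on |AR| with add-one correction.

    p = (1 + #{null |AR| >= observed |AR|}) / (1 + n_valid).  With ``pool``
    each interval is compared against the null draws of all intervals
    combined (smaller Monte-Carlo error, assumes a common null shape).
    Untestable intervals (NaN AR) get NaN.
    """
    observed = np.asarray(observed, dtype=float)
    null = np.asarray(null, dtype=float)
    if null.ndim != 2 or null.shape[1] != observed.shape[0]:
        raise ValueError("null must be n_draws x n_intervals")
    if null.shape[0] < 1:
        raise ValueError("need at least one null draw per interval")
    abs_null = np.abs(null)
    p = np.full(observed.shape, np.nan)
    pooled = abs_null[np.isfinite(abs_null)] if pool else None
    for i, obs in enumerate(np.abs(observed)):
        if not np.isfinite(obs):
            continue
        ref = pooled if pool else abs_null[:, i][np.isfinite(abs_null[:, i])]
        if ref.size == 0:
            continue
        p[i] = (1.0 + np.sum(ref >= obs - 1e-12)) / (1.0 + ref.size)
    return p


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _merge_significant(results: list[IntervalResult]
                       ) -> list[tuple[float, float, str]]:
    """Merge adjacent significant intervals sharing the dominant group."""
    merged: list[tuple[float, float, str]] = []
    for r in results:
        if not (r.significant and r.dominant_group):
            continue
        if (merged and merged[-1][2] == r.dominant_group
                and abs(merged[-1][1] - r.start) < 1e-9):
            merged[-1] = (merged[-1][0], r.end, r.dominant_group)
        else:
            merged.append((r.start, r.end, r.dominant_group))
    return merged


def run_feature_test(series: FeatureSeries, grid: TimeGrid,
                     config: TestConfig | None = None,
                     smoother: SmootherConfig | None = None
                     ) -> FeatureTestResult:
    """Full per-feature test: fit, permute, p-values, BH, merged spans.

    Untestable features (degenerate fits, excessive permutation failures)
    are reported with a reason instead of raising.  With
    ``config.adjust_scope == "global"`` the per-feature BH step is skipped;
    call :func:`apply_global_adjustment` on the collected results instead.
    """
    config = config or TestConfig()
    smoother = smoother or SmootherConfig()
    levels = tuple(series.group_levels)
    if len(levels) != 2:
        return FeatureTestResult(series.feature_id, ("", ""), [], [],
                                 untestable_reason=f"groups found: {levels}")
    try:
        fit1, fit2, a1, a2, ar = _observed_ar(series, grid, smoother, levels)
        lambdas = None
        if isinstance(fit1, NBSplineFit):
            lambdas = (fit1.lambda_rel, fit2.lambda_rel)
        null, failures = permutation_null(series, grid, config, smoother,
                                          lambdas=lambdas)
    except (FitError, np.linalg.LinAlgError) as e:
        return FeatureTestResult(series.feature_id, levels, [], [],
                                 untestable_reason=str(e))
    pvals = interval_pvalues(ar, null, pool=config.pool_null)
    if config.adjust_scope == "per_feature":
        padj = adjust_bh(pvals)
    else:
        padj = np.full(pvals.shape, np.nan)
    results = []
    for i, (t0, t1) in enumerate(grid.intervals):
        testable = np.isfinite(ar[i])
        sig = bool(testable and np.isfinite(padj[i])
                   and padj[i] < config.p_threshold)
        if not testable or ar[i] == 0:
            dom = None
        else:
            dom = levels[0] if ar[i] > 0 else levels[1]
        results.append(IntervalResult(
            feature_id=series.feature_id, start=t0, end=t1,
            area_group1=float(a1[i]), area_group2=float(a2[i]),
            ar=float(ar[i]), pvalue=float(pvals[i]),
            adjusted_pvalue=float(padj[i]), dominant_group=dom,
            significant=sig, testable=bool(testable)))
    return FeatureTestResult(
        series.feature_id, levels, results, _merge_significant(results),
        n_failed_permutations=failures, lambdas=lambdas)


def apply_global_adjustment(features: list[FeatureTestResult],
                            p_threshold: float = 0.05) -> None:
    """BH-adjust p-values jointly across all features' intervals, in place."""
    flat = [r for f in features for r in f.intervals if r.testable]
    if not flat:
        return
    padj = adjust_bh([r.pvalue for r in flat])
    for r, q in zip(flat, padj):
        r.adjusted_pvalue = float(q)
        r.significant = bool(np.isfinite(q) and q < p_threshold)
    for f in features:
        f.merged = _merge_significant(f.intervals)
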