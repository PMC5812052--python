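"""Synthetic longitudinal count data with known differential intervals.

Each feature is observed on the integer grid t = 0..20 for 15 subjects per
group.  A differentially abundant (DA) feature has group-B mean
mu_B(t) = 30 + 10 sin(pi t / 20) and group-A mean mu_A(t) = g(t) * mu_B(t),
where the smooth gain g(t) rises to 2.5 inside each of the three DA regions
[1,5], [8,13] and [15,20] and is exactly 1 on the non-differential spans
[5,8] and [13,15] (C^1 piecewise-cosine ramps).  Null features use one
constant level for both groups, drawn per feature from Normal(30, 5)
truncated below at 5.

Within-subject correlation between adjacent time points follows a Gaussian
copula: a latent standard AR(1) series with coefficient rho = 0.9 is pushed
through the normal CDF and then the inverse CDF of the target marginal —
negative binomial with mean mu(t) and size 40/mu(t), Poisson with
lambda = mu(t), or zero-inflated Poisson with zero-inflation 0.3.  The
transform is monotone, so the count-scale autocorrelation is slightly below
rho; rho refers to the latent series.

Two sampling designs are provided: ``consistent`` (every subject sampled at
every time point) and ``inconsistent`` (per feature, group A keeps 8 randomly
chosen subjects with 11 randomly chosen sample times each, group B keeps 6
subjects with 8 sample times each, mimicking cohorts with unequal subjects
per group, unequal samples per subject and unevenly spaced samples).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr

from .core_data import CountTable, FeatureSeries, SampleMetadata
from .interval_test import (
    FeatureTestResult, TestConfig, build_time_grid, run_feature_test,
)
from .nb_spline import SmootherConfig

__all__ = [
    "SimulationConfig", "SimulatedDataset", "BenchmarkReport",
    "DA_REGIONS", "NULL_REGIONS",
    "mean_patterns", "correlated_counts", "make_dataset", "score_detector",
    "run_benchmark",
]

DA_REGIONS = ((1.0, 5.0), (8.0, 13.0), (15.0, 20.0))
NULL_REGIONS = ((5.0, 8.0), (13.0, 15.0))


@dataclass
class SimulationConfig:
    """Study conditions of the simulation benchmark."""

    marginal: str = "nb"                  # nb | poisson | zip
    n_da_features: int = 100
    n_null_features: int = 100
    n_subjects_per_group: int = 15
    t_max: int = 20                       # samples at t = 0..t_max
    rho: float = 0.9
    nb_size_scale: float = 40.0           # NB size = 40 / mu(t)
    zip_zero_prob: float = 0.3
    design: str = "consistent"            # or "inconsistent"
    # (n_subjects, n_samples_per_subject) per group, inconsistent design
    inconsistent_spec: tuple[tuple[int, int], tuple[int, int]] = ((8, 11), (6, 8))
    freeze_design: bool = False           # one subsampling shared by features
    da_gain: float = 2.5
    ramp_width: float = 1.0
    null_level_mean: float = 30.0
    null_level_sd: float = 5.0
    null_level_floor: float = 5.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.marginal not in ("nb", "poisson", "zip"):
            raise ValueError(f"unknown marginal {self.marginal!r}")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        if self.design not in ("consistent", "inconsistent"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.design == "inconsistent":
            for (n_subj, n_per) in self.inconsistent_spec:
                if n_subj > self.n_subjects_per_group:
                    raise ValueError("more subjects requested than available")
                if n_per > self.t_max + 1:
                    raise ValueError(
                        "more samples per subject than available time points")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.t_max + 1, dtype=float)

    @property
    def n_intervals(self) -> int:
        """Unit intervals of the ground-truth domain [1, t_max]."""
        return self.t_max - 1


def _cos_ramp(x: np.ndarray) -> np.ndarray:
    """C^1 ramp from 0 at x=0 to 1 at x=1."""
    return 0.5 * (1.0 - np.cos(np.pi * np.clip(x, 0.0, 1.0)))


def _da_gain_curve(t: np.ndarray, gain: float, width: float,
                   t_max: float) -> np.ndarray:
    g = np.zeros_like(t, dtype=float)
    for a, b in DA_REGIONS:
        w = min(width, (b - a) / 2.0)
        r = np.zeros_like(t)
        inside = (t >= a) & (t <= b)
        r[inside] = 1.0
        up = inside & (t < a + w)
        r[up] = _cos_ramp((t[up] - a) / w)
        if b < t_max:  # the last region runs to the end of the study
            down = inside & (t > b - w)
            r[down] = np.minimum(r[down], _cos_ramp((b - t[down]) / w))
        g += r
    return 1.0 + (gain - 1.0) * g


def mean_patterns(da: bool, t, gain: float = 2.5, ramp_width: float = 1.0,
                  null_level: float = 30.0, t_max: float = 20.0,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Group mean trajectories (mu_A, mu_B) at the given times.

    DA features separate (peak ratio `gain`) inside the three DA regions and
    coincide exactly on the non-differential spans; null features share one
    constant level.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0) or np.any(t > t_max):
        raise ValueError(f"times must lie in [0, {t_max}]")
    if not da:
        mu = np.full_like(t, float(null_level))
        return mu, mu.copy()
    mu_b = 30.0 + 10.0 * np.sin(np.pi * t / t_max)
    mu_a = _da_gain_curve(t, gain, ramp_width, t_max) * mu_b
    return mu_a, mu_b


def _marginal_ppf(u: np.ndarray, mu: np.ndarray,
                  config: SimulationConfig) -> np.ndarray:
    if np.any(mu <= 0):
        raise ValueError("marginal means must be strictly positive")
    if config.marginal == "nb":
        size = config.nb_size_scale / mu
        return stats.nbinom.ppf(u, size, size / (size + mu))
    if config.marginal == "poisson":
        return stats.poisson.ppf(u, mu)
    # zero-inflated Poisson: F(y) = p0 + (1 - p0) * F_pois(y)
    p0 = config.zip_zero_prob
    out = np.zeros(np.broadcast_shapes(u.shape, np.shape(mu)))
    hot = u > p0
    u_adj = (u - p0) / (1.0 - p0)
    out[hot] = stats.poisson.ppf(u_adj[hot], np.broadcast_to(mu, out.shape)[hot])
    return out


def _latent_ar1(rng: np.random.Generator, shape: tuple[int, ...],
                rho: float) -> np.ndarray:
    """Stationary standard-normal AR(1) series along the last axis."""
    z = rng.standard_normal(shape)
    innov = np.sqrt(1.0 - rho * rho)
    for t in range(1, shape[-1]):
        z[..., t] = rho * z[..., t - 1] + innov * z[..., t]
    return z


def correlated_counts(mu, marginal: str | None = None, rho: float | None = None,
                      config: SimulationConfig | None = None,
                      seed: int | np.random.Generator = 0) -> np.ndarray:
    """One subject's correlated count series for means mu(t).

    Latent standard AR(1) Gaussian -> normal CDF -> inverse CDF of the
    target marginal at each time.  The copula transform is monotone in the
    latent value.
    """
    config = config or SimulationConfig()
    if marginal is not None:
        config = SimulationConfig(**{**config.__dict__, "marginal": marginal})
    rho = config.rho if rho is None else rho
    mu = np.asarray(mu, dtype=float)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    z = _latent_ar1(rng, (1, len(mu)), rho)
    u = np.clip(ndtr(z), 1e-12, 1 - 1e-12)
    return _marginal_ppf(u, mu[None, :], config)[0]


def _truth_mask(da: bool, t_max: int) -> np.ndarray:
    """Boolean mask over unit intervals [t, t+1], t = 1..t_max-1."""
    starts = np.arange(1, t_max, dtype=float)
    if not da:
        return np.zeros(len(starts), dtype=bool)
    mask = np.zeros(len(starts), dtype=bool)
    for a, b in DA_REGIONS:
        mask |= (starts >= a - 1e-9) & (starts + 1 <= b + 1e-9)
    return mask


@dataclass
class SimulatedDataset:
    """Simulated counts, metadata, per-feature ground truth and (for the
    inconsistent design) per-feature retained-sample masks."""

    table: CountTable
    meta: list[SampleMetadata]
    truth: dict[str, np.ndarray]
    config: SimulationConfig
    sample_masks: dict[str, np.ndarray] | None = None

    def meta_for_feature(self, feature_id: str) -> list[SampleMetadata]:
        if self.sample_masks is None:
            return self.meta
        mask = self.sample_masks[feature_id]
        return [m for m, keep in zip(self.meta, mask) if keep]

    def feature_series(self, feature_id: str,
                       table: CountTable | None = None) -> FeatureSeries:
        table = table if table is not None else self.table
        row = table.row(feature_id)
        if self.sample_masks is not None:
            mask = self.sample_masks[feature_id]
            meta = [m for m, keep in zip(self.meta, mask) if keep]
            row = row[mask]
        else:
            meta = self.meta
        return FeatureSeries(
            feature_id,
            times=[m.time for m in meta],
            groups=[m.group for m in meta],
            subjects=[m.subject_id for m in meta],
            counts=row)


def _subsample_group(rng: np.random.Generator, n_subjects_avail: int,
                     n_subjects: int, n_per_subject: int, n_times: int
                     ) -> list[tuple[int, int]]:
    """Pick (subject index, time index) slots: n_subjects subjects, each
    keeping n_per_subject randomly chosen sample times."""
    subjects = rng.choice(n_subjects_avail, size=n_subjects, replace=False)
    slots = []
    for s in subjects:
        for ti in rng.choice(n_times, size=n_per_subject, replace=False):
            slots.append((int(s), int(ti)))
    return slots


def make_dataset(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Simulate the full benchmark dataset with ground-truth interval masks."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.rng_seed)
    times = config.times
    T1 = len(times)
    n_subj = config.n_subjects_per_group
    groups = ("A", "B")

    feature_ids = ([f"da_{i + 1:04d}" for i in range(config.n_da_features)]
                   + [f"null_{i + 1:04d}" for i in range(config.n_null_features)])
    n_feat = len(feature_ids)
    da_flags = np.r_[np.ones(config.n_da_features, dtype=bool),
                     np.zeros(config.n_null_features, dtype=bool)]

    # per-feature group means, shape (n_feat, 2, T+1)
    mu = np.empty((n_feat, 2, T1))
    null_levels = np.maximum(
        rng.normal(config.null_level_mean, config.null_level_sd, size=n_feat),
        config.null_level_floor)
    for i, da in enumerate(da_flags):
        mu_a, mu_b = mean_patterns(bool(da), times, gain=config.da_gain,
                                   ramp_width=config.ramp_width,
                                   null_level=null_levels[i],
                                   t_max=config.t_max)
        mu[i, 0], mu[i, 1] = mu_a, mu_b

    meta: list[SampleMetadata] = []
    sample_ids: list[str] = []
    for gi, g in enumerate(groups):
        for s in range(n_subj):
            subj = f"{g}{s + 1:02d}"
            for ti, t in enumerate(times):
                sid = f"{subj}_t{int(t):02d}"
                sample_ids.append(sid)
                meta.append(SampleMetadata(sid, subj, g, float(t)))

    # latent AR(1) per (feature, group, subject), counts via the copula
    counts = np.empty((n_feat, len(sample_ids)))
    col = 0
    for gi, g in enumerate(groups):
        z = _latent_ar1(rng, (n_feat, n_subj, T1), config.rho)
        u = np.clip(ndtr(z), 1e-12, 1 - 1e-12)
        c = _marginal_ppf(u, mu[:, gi, None, :], config)
        counts[:, col:col + n_subj * T1] = c.reshape(n_feat, n_subj * T1)
        col += n_subj * T1

    truth = {fid: _truth_mask(bool(da), config.t_max)
             for fid, da in zip(feature_ids, da_flags)}
    table = CountTable(counts, feature_ids, sample_ids)

    masks = None
    if config.design == "inconsistent":
        masks = {}
        frozen: np.ndarray | None = None
        for fi, fid in enumerate(feature_ids):
            if frozen is not None:
                masks[fid] = frozen
                continue
            mask = np.zeros(len(sample_ids), dtype=bool)
            for gi, (n_sub, n_per) in enumerate(config.inconsistent_spec):
                base = gi * n_subj * T1
                for s, ti in _subsample_group(rng, n_subj, n_sub, n_per, T1):
                    mask[base + s * T1 + ti] = True
            masks[fid] = mask
            if config.freeze_design:
                frozen = mask
    return SimulatedDataset(table, meta, truth, config, masks)


@dataclass
class BenchmarkReport:
    """Per-feature sensitivity/specificity and their mean and SD."""

    per_feature: pd.DataFrame        # feature_id, da, sensitivity, specificity
    mean_sensitivity: float
    sd_sensitivity: float
    mean_specificity: float
    sd_specificity: float
    n_features: int
    n_untestable: int

    def summary(self) -> dict[str, float]:
        return {
            "mean_sensitivity": self.mean_sensitivity,
            "sd_sensitivity": self.sd_sensitivity,
            "mean_specificity": self.mean_specificity,
            "sd_specificity": self.sd_specificity,
            "n_features": self.n_features,
            "n_untestable": self.n_untestable,
        }


def score_detector(results: dict[str, FeatureTestResult],
                   truth: dict[str, np.ndarray]) -> BenchmarkReport:
    """Score interval calls against the ground-truth masks.

    Only intervals inside the truth domain (unit intervals [t, t+1] with
    integer t in 1..T-1) are scored; intervals a feature could not test
    (outside its overlap range, or the whole feature untestable) count as
    not called.  Per feature, sensitivity = TP/(TP+FN) over truth-positive
    intervals and specificity = TN/(TN+FP) over truth-negative intervals;
    the report averages across features.
    """
    rows = []
    n_untestable = 0
    for fid, mask in truth.items():
        if fid not in results:
            raise ValueError(f"no test result for feature {fid!r}")
        res = results[fid]
        n_int = len(mask)
        called = np.zeros(n_int, dtype=bool)
        tested = np.zeros(n_int, dtype=bool)
        if not res.testable:
            n_untestable += 1
        else:
            for r in res.intervals:
                if abs(r.start - round(r.start)) > 1e-6 or \
                        abs(r.end - r.start - 1.0) > 1e-6:
                    raise ValueError(
                        f"feature {fid!r}: interval [{r.start}, {r.end}] does "
                        "not align with the unit-interval truth grid")
                s = int(round(r.start))
                if 1 <= s <= n_int:
                    tested[s - 1] = True
                    called[s - 1] = r.significant
        pos, neg = mask, ~mask
        tp = int(np.sum(called & pos))
        fn = int(np.sum(~called & pos))
        tn = int(np.sum(~called & neg))
        fp = int(np.sum(called & neg))
        sens = tp / (tp + fn) if (tp + fn) else np.nan
        spec = tn / (tn + fp) if (tn + fp) else np.nan
        rows.append({"feature_id": fid, "da": bool(mask.any()),
                     "n_tested": int(tested.sum()),
                     "tp": tp, "fn": fn, "tn": tn, "fp": fp,
                     "sensitivity": sens, "specificity": spec})
    df = pd.DataFrame(rows)
    sens = df["sensitivity"].dropna()
    spec = df["specificity"].dropna()
    return BenchmarkReport(
        per_feature=df,
        mean_sensitivity=float(sens.mean()) if len(sens) else float("nan"),
        sd_sensitivity=float(sens.std(ddof=0)) if len(sens) else float("nan"),
        mean_specificity=float(spec.mean()) if len(spec) else float("nan"),
        sd_specificity=float(spec.std(ddof=0)) if len(spec) else float("nan"),
        n_features=len(df), n_untestable=n_untestable)


def _feature_seed(master: int, index: int) -> int:
    return int(np.random.SeedSequence([master, index]).generate_state(1)[0]
               % (2 ** 31))


def run_benchmark(dataset: SimulatedDataset,
                  test_config: TestConfig | None = None,
                  smoother: SmootherConfig | None = None,
                  progress: bool = False,
                  ) -> tuple[dict[str, FeatureTestResult], BenchmarkReport]:
    """Run the interval test on every simulated feature and score it.

    Per-feature RNG seeds are derived deterministically from the master seed
    and the feature index, so results are reproducible and independent of
    execution order.
    """
    test_config = test_config or TestConfig(n_permutations=200)
    smoother = smoother or SmootherConfig()
    results: dict[str, FeatureTestResult] = {}
    for i, fid in enumerate(dataset.table.feature_ids):
        series = dataset.feature_series(fid)
        meta_f = dataset.meta_for_feature(fid)
        cfg = TestConfig(**{**test_config.__dict__,
                            "rng_seed": _feature_seed(test_config.rng_seed, i)})
        try:
            grid = build_time_grid(meta_f)
            results[fid] = run_feature_test(series, grid, cfg, smoother)
        except ValueError as e:
            results[fid] = FeatureTestResult(
                fid, ("A", "B"), [], [], untestable_reason=str(e))
        if progress and (i + 1) % 20 == 0:
            print(f"  tested {i + 1}/{dataset.table.m} features", flush=True)
    return results, score_detector(results, dataset.truth)
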