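"""Between-sample normalization of the count table.

Sequencing depth differs between samples, so counts are rescaled before any
modeling.  Three scaling-factor methods are provided:

* ``css`` — cumulative sum scaling: each sample is scaled by the sum of its
  counts up to a sample-specific quantile, robust to a few dominant features.
* ``median_ratio`` — median-of-ratios: the median, over features detected in
  every sample, of the ratio between a sample's count and the feature's
  geometric-mean reference.
* ``tmm`` — trimmed mean of M-values: a doubly trimmed, precision-weighted
  mean of per-feature log2 ratios against a reference sample.

Normalization divides the counts directly (``apply_normalization``); the
downstream negative-binomial model is then fitted to the normalized counts
rather than folding a size factor into the model mean.  A table that is
already normalized can use method ``none``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import CountTable

__all__ = [
    "ScalingFactors", "css_factors", "median_ratio_factors", "tmm_factors",
    "apply_normalization", "normalize", "NORM_METHODS",
]

NORM_METHODS = ("css", "median_ratio", "tmm", "none")


@dataclass
class ScalingFactors:
    """Per-sample positive scaling factors; counts are divided by these."""

    factors: dict[str, float]
    method: str

    def __post_init__(self) -> None:
        if self.method not in NORM_METHODS:
            raise ValueError(f"unknown normalization method {self.method!r}")
        for s, f in self.factors.items():
            if not np.isfinite(f) or f <= 0:
                raise ValueError(f"non-positive factor {f} for sample {s!r}")

    def as_array(self, sample_ids: list[str]) -> np.ndarray:
        try:
            return np.asarray([self.factors[s] for s in sample_ids])
        except KeyError as e:
            raise ValueError(f"no scaling factor for sample {e.args[0]!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": list(self.factors),
                             "factor": list(self.factors.values())})


def css_factors(table: CountTable, quantile: float = 0.5) -> ScalingFactors:
    """Cumulative-sum-scaling factors at the given quantile (default median).

    The factor for a sample is the sum of its counts that are at or below
    the sample's `quantile`-th count value; factors are rescaled so their
    median is 1, keeping normalized counts on the raw-count scale.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    raw = np.empty(table.n)
    for j in range(table.n):
        col = table.counts[:, j]
        if not np.any(col > 0):
            raise ValueError(f"sample {table.sample_ids[j]!r} is all zeros")
        cutoff = np.quantile(col, quantile)
        raw[j] = col[col <= cutoff].sum()
        if raw[j] <= 0:
            # every count above the cutoff: fall back to the cutoff itself
            raw[j] = max(cutoff, col[col > 0].min())
    factors = raw / np.median(raw)
    return ScalingFactors(dict(zip(table.sample_ids, factors)), "css")


def median_ratio_factors(table: CountTable) -> ScalingFactors:
    """Median-of-ratios factors against per-feature geometric-mean references.

    Only features with strictly positive counts in every sample enter the
    reference set.
    """
    counts = table.counts
    positive = np.all(counts > 0, axis=1)
    if not positive.any():
        raise ValueError(
            "no feature has nonzero counts in every sample; "
            "median-of-ratios is undefined (consider CSS instead)")
    ref_rows = counts[positive]
    log_ref = np.mean(np.log(ref_rows), axis=1)          # log geometric mean
    ratios = np.log(ref_rows) - log_ref[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return ScalingFactors(dict(zip(table.sample_ids, factors)), "median_ratio")


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, log_ratio_trim: float,
              abs_expr_trim: float) -> float:
    """TMM factor of one sample against the reference (log2 scale -> linear)."""
    n_obs, n_ref = obs.sum(), ref.sum()
    ok = (obs > 0) & (ref > 0)
    if not ok.any():
        raise ValueError("no feature is nonzero in both sample and reference")
    o, r = obs[ok], ref[ok]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    # asymptotic binomial variance of M
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)

    n = len(m)
    lo_m = np.floor(n * log_ratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_expr_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = np.argsort(np.argsort(m, kind="stable"), kind="stable") + 1
    rank_a = np.argsort(np.argsort(a, kind="stable"), kind="stable") + 1
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & \
           (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(2.0 ** f)


def tmm_factors(table: CountTable, log_ratio_trim: float = 0.30,
                abs_expr_trim: float = 0.05) -> ScalingFactors:
    """Trimmed-mean-of-M-values factors, rescaled to geometric mean 1.

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the mean across samples.  Zero-count features are excluded
    from the M-value computation.
    """
    counts = table.counts
    lib = counts.sum(axis=0)
    if np.any(lib <= 0):
        j = int(np.argmax(lib <= 0))
        raise ValueError(f"sample {table.sample_ids[j]!r} is all zeros")
    uq = np.array([np.quantile(counts[:, j] / lib[j], 0.75)
                   for j in range(table.n)])
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    ref = counts[:, ref_idx]
    factors = np.array([
        1.0 if j == ref_idx else
        _tmm_pair(counts[:, j], ref, log_ratio_trim, abs_expr_trim)
        for j in range(table.n)
    ])
    factors /= np.exp(np.mean(np.log(factors)))
    return ScalingFactors(dict(zip(table.sample_ids, factors)), "tmm")


def apply_normalization(table: CountTable, factors: ScalingFactors) -> CountTable:
    """Divide each sample's counts by its factor; ``none`` returns the table."""
    if factors.method == "none":
        return table
    f = factors.as_array(table.sample_ids)
    return CountTable(table.counts / f[None, :], list(table.feature_ids),
                      list(table.sample_ids))


def normalize(table: CountTable, method: str = "css",
              **kwargs) -> tuple[CountTable, ScalingFactors]:
    """Compute factors with `method` and apply them; ``none`` is a no-op."""
    if method == "css":
        factors = css_factors(table, **kwargs)
    elif method == "median_ratio":
        factors = median_ratio_factors(table, **kwargs)
    elif method == "tmm":
        factors = tmm_factors(table, **kwargs)
    elif method == "none":
        factors = ScalingFactors({s: 1.0 for s in table.sample_ids}, "none")
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return apply_normalization(table, factors), factors
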