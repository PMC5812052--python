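"""Parametric-distribution suitability checks for per-feature counts.

For each feature the counts are fitted by maximum likelihood to a set of
candidate distributions (negative binomial, zero-inflated Poisson, Poisson,
lognormal, exponential, half-normal, normal).  Suitability is judged with a
two-sample Kolmogorov-Smirnov test between the observed counts and a sample
drawn from the fitted distribution; a feature/distribution pair is adequate
when the BH-adjusted KS p-value exceeds 0.05 (adjusted within each
distribution family across features).  The discrete families inherit the
conservatism of the two-sample KS statistic under ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .core_data import CountTable
from .interval_test import adjust_bh

__all__ = [
    "DISTRIBUTIONS", "DistFitResult", "FitSummary",
    "fit_distribution", "sample_distribution", "ks_adequacy",
    "evaluate_feature", "evaluate_table", "summarize_fits",
]

DISTRIBUTIONS = ("nb", "zip", "poisson", "lognormal", "exponential",
                 "halfnormal", "normal")


class DegenerateDataError(ValueError):
    """All observations identical: scale-requiring families cannot be fit."""


def _check(counts: np.ndarray, distribution: str) -> np.ndarray:
    y = np.asarray(counts, dtype=float)
    if y.size < 10:
        raise ValueError("need at least 10 observations to fit")
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if distribution != "poisson" and np.ptp(y) == 0:
        raise DegenerateDataError(
            f"all observations identical; cannot fit {distribution!r}")
    return y


def _fit_nb(y: np.ndarray) -> dict[str, float]:
    """NB MLE in the (mean, shape) parameterization.

    The profile MLE of the mean is the sample mean; the shape maximizes the
    profile log-likelihood, found on the log scale.
    """
    mean = float(np.mean(y))
    if mean <= 0:
        raise DegenerateDataError("all-zero counts")

    def nll(log_shape: float) -> float:
        r = np.exp(log_shape)
        p = r / (r + mean)
        return -float(np.sum(stats.nbinom.logpmf(np.round(y), r, p)))

    res = minimize_scalar(nll, bounds=(np.log(1e-3), np.log(1e5)),
                          method="bounded",
                          options={"xatol": 1e-6})
    return {"mean": mean, "shape": float(np.exp(res.x))}


def _fit_zip(y: np.ndarray) -> dict[str, float]:
    """ZIP MLE via the profile in the Poisson rate.

    For a given rate lam the MLE of the zero-inflation weight has a closed
    form from the observed zero fraction; the rate is optimized numerically.
    """
    mean = float(np.mean(y))
    if mean <= 0:
        raise DegenerateDataError("all-zero counts")
    yr = np.round(y)
    n = len(yr)
    n0 = int(np.sum(yr == 0))
    pos = yr[yr > 0]

    def nll(log_lam: float) -> float:
        lam = np.exp(log_lam)
        p_pois0 = np.exp(-lam)
        # pi maximizing the likelihood given lam (clipped to [0, 1))
        pi = (n0 / n - p_pois0) / (1.0 - p_pois0)
        pi = float(np.clip(pi, 0.0, 1 - 1e-12))
        ll0 = n0 * np.log(pi + (1 - pi) * p_pois0) if n0 else 0.0
        llp = float(np.sum(np.log1p(-pi) + stats.poisson.logpmf(pos, lam)))
        return -(ll0 + llp)

    res = minimize_scalar(nll, bounds=(np.log(max(mean, 1e-6)) - 3,
                                       np.log(max(mean, 1e-6)) + 3),
                          method="bounded", options={"xatol": 1e-8})
    lam = float(np.exp(res.x))
    p_pois0 = np.exp(-lam)
    pi = float(np.clip((n0 / n - p_pois0) / (1.0 - p_pois0), 0.0, 1 - 1e-12))
    return {"zero_prob": pi, "rate": lam}


def fit_distribution(counts, distribution: str) -> dict[str, float]:
    """Maximum-likelihood parameter estimates for one candidate family.

    Lognormal is fitted to counts + 1 so zeros do not break its support.
    """
    if distribution not in DISTRIBUTIONS:
        raise ValueError(f"unknown distribution {distribution!r}")
    y = _check(counts, distribution)
    if distribution == "nb":
        return _fit_nb(y)
    if distribution == "zip":
        return _fit_zip(y)
    if distribution == "poisson":
        return {"rate": float(np.mean(y))}
    if distribution == "lognormal":
        logy = np.log(y + 1.0)
        return {"mu": float(np.mean(logy)),
                "sigma": float(max(np.std(logy), 1e-9))}
    if distribution == "exponential":
        return {"scale": float(np.mean(y))}
    if distribution == "halfnormal":
        return {"scale": float(np.sqrt(np.mean(y ** 2)))}
    return {"mean": float(np.mean(y)), "sd": float(np.std(y))}


def sample_distribution(distribution: str, params: dict[str, float],
                        size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw from a fitted family (used as the KS comparator sample)."""
    if distribution == "nb":
        r = params["shape"]
        p = r / (r + params["mean"])
        return rng.negative_binomial(r, p, size=size).astype(float)
    if distribution == "zip":
        lam, pi = params["rate"], params["zero_prob"]
        x = rng.poisson(lam, size=size).astype(float)
        x[rng.random(size) < pi] = 0.0
        return x
    if distribution == "poisson":
        return rng.poisson(params["rate"], size=size).astype(float)
    if distribution == "lognormal":
        return np.exp(rng.normal(params["mu"], params["sigma"], size)) - 1.0
    if distribution == "exponential":
        return rng.exponential(params["scale"], size)
    if distribution == "halfnormal":
        return np.abs(rng.normal(0.0, params["scale"], size))
    if distribution == "normal":
        return rng.normal(params["mean"], params["sd"], size)
    raise ValueError(f"unknown distribution {distribution!r}")


def ks_adequacy(counts, distribution: str, params: dict[str, float],
                n_sample: int | None = None,
                seed: int | np.random.Generator = 0) -> tuple[float, float]:
    """Two-sample KS statistic and p-value: observed counts vs a sample
    drawn from the fitted distribution (comparator size defaults to the
    observed sample size)."""
    y = np.asarray(counts, dtype=float)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n_sample = n_sample or len(y)
    comparator = sample_distribution(distribution, params, n_sample, rng)
    res = stats.ks_2samp(y, comparator)
    return float(res.statistic), float(res.pvalue)


@dataclass
class DistFitResult:
    """KS outcome for one feature under one candidate distribution."""

    feature_id: str
    distribution: str
    params: dict[str, float]
    ks_stat: float
    pvalue: float
    adjusted_pvalue: float = float("nan")
    adequate: bool = False
    error: str | None = None


@dataclass
class FitSummary:
    """Per-family counts/percentages of features judged adequately modeled."""

    n_features: int
    table: pd.DataFrame      # distribution, n_adequate, percent_adequate


def evaluate_feature(feature_id: str, counts,
                     distributions=DISTRIBUTIONS,
                     n_sample: int | None = None,
                     seed: int | np.random.Generator = 0
                     ) -> list[DistFitResult]:
    """Fit and KS-check one feature's counts under each candidate family."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    out = []
    for dist in distributions:
        try:
            params = fit_distribution(counts, dist)
            ks, p = ks_adequacy(counts, dist, params, n_sample, rng)
            out.append(DistFitResult(feature_id, dist, params, ks, p))
        except (ValueError, FloatingPointError) as e:
            out.append(DistFitResult(feature_id, dist, {}, float("nan"),
                                     float("nan"), error=str(e)))
    return out


def evaluate_table(table: CountTable, distributions=DISTRIBUTIONS,
                   n_sample: int | None = None,
                   seed: int = 0, alpha: float = 0.05
                   ) -> list[DistFitResult]:
    """Evaluate every feature; BH-adjust within each family across features."""
    results: list[DistFitResult] = []
    for i, fid in enumerate(table.feature_ids):
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2 ** 31))
        results.extend(evaluate_feature(fid, table.row(fid), distributions,
                                        n_sample, rng))
    for dist in distributions:
        fam = [r for r in results if r.distribution == dist and r.error is None]
        if not fam:
            continue
        padj = adjust_bh([r.pvalue for r in fam])
        for r, q in zip(fam, padj):
            r.adjusted_pvalue = float(q)
            r.adequate = bool(np.isfinite(q) and q > alpha)
    return results


def summarize_fits(results: list[DistFitResult],
                   n_features: int | None = None) -> FitSummary:
    """Count, per family, how many features it models adequately."""
    if n_features is None:
        n_features = len({r.feature_id for r in results})
    rows = []
    for dist in DISTRIBUTIONS:
        fam = [r for r in results if r.distribution == dist]
        if not fam:
            continue
        n_ok = sum(r.adequate for r in fam)
        pct = 100.0 * n_ok / n_features if n_features else float("nan")
        rows.append({"distribution": dist, "n_adequate": n_ok,
                     "percent_adequate": pct})
    return FitSummary(n_features=n_features, table=pd.DataFrame(rows))


def qq_data(counts, distribution: str, params: dict[str, float],
            seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Sample-vs-theoretical quantile pairs for a quantile-quantile plot.

    Theoretical quantiles come from a sample drawn from the fitted
    distribution, matching how adequacy itself is judged.
    """
    y = np.sort(np.asarray(counts, dtype=float))
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    theo = np.sort(sample_distribution(distribution, params, len(y), rng))
    return pd.DataFrame({"quantile": (np.arange(len(y)) + 0.5) / len(y),
                         "sample": y, "theoretical": theo})


def results_frame(results: list[DistFitResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "feature_id": r.feature_id, "distribution": r.distribution,
        "ks_stat": r.ks_stat, "pvalue": r.pvalue,
        "adjusted_pvalue": r.adjusted_pvalue, "adequate": r.adequate,
        "params": ";".join(f"{k}={v:.6g}" for k, v in r.params.items()),
        "error": r.error or "",
    } for r in results])
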