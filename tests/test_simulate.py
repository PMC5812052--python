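import numpy as np
import pytest
from scipy import stats

from longinterval.interval_test import FeatureTestResult, IntervalResult
from longinterval.simulate import (
    DA_REGIONS, SimulationConfig, _latent_ar1, _marginal_ppf,
    correlated_counts, make_dataset, mean_patterns, score_detector,
)


class TestMeanPatterns:
    def test_null_features_share_one_curve(self):
        t = np.linspace(0, 20, 81)
        mu_a, mu_b = mean_patterns(False, t, null_level=12.0)
        np.testing.assert_array_equal(mu_a, mu_b)
        assert np.all(mu_a == 12.0)

    def test_curves_coincide_on_non_differential_spans(self):
        for t in [5.0, 6.5, 7.9, 13.0, 14.2, 15.0, 0.5, 1.0]:
            mu_a, mu_b = mean_patterns(True, [t])
            assert mu_a[0] == pytest.approx(mu_b[0], rel=1e-12), t

    def test_separation_inside_differential_regions(self):
        for t in [3.0, 10.5, 17.5]:
            mu_a, mu_b = mean_patterns(True, [t])
            assert mu_a[0] / mu_b[0] >= 2.0, t

    def test_positive_and_continuous(self):
        t = np.linspace(0, 20, 4001)
        mu_a, mu_b = mean_patterns(True, t)
        assert np.all(mu_a > 0) and np.all(mu_b > 0)
        assert np.max(np.abs(np.diff(mu_a))) < 0.5  # no jumps at 5e-3 spacing


class TestLatentAR1:
    def test_lag_one_correlation_matches_rho(self):
        rng = np.random.default_rng(0)
        z = _latent_ar1(rng, (2000, 21), 0.9)
        r = np.corrcoef(z[:, :-1].ravel(), z[:, 1:].ravel())[0, 1]
        assert r == pytest.approx(0.9, abs=0.05)

    def test_zero_rho_is_independent(self):
        rng = np.random.default_rng(1)
        z = _latent_ar1(rng, (2000, 21), 0.0)
        r = np.corrcoef(z[:, :-1].ravel(), z[:, 1:].ravel())[0, 1]
        assert abs(r) < 0.1

    def test_marginals_stay_standard_normal(self):
        rng = np.random.default_rng(2)
        z = _latent_ar1(rng, (4000, 21), 0.9)
        assert np.mean(z[:, -1]) == pytest.approx(0.0, abs=0.06)
        assert np.std(z[:, -1]) == pytest.approx(1.0, abs=0.05)


class TestCorrelatedCounts:
    @pytest.mark.parametrize("marginal,dist", [
        ("nb", lambda mu: stats.nbinom(40 / mu, (40 / mu) / (40 / mu + mu))),
        ("poisson", lambda mu: stats.poisson(mu)),
    ])
    def test_marginal_fidelity_at_fixed_time(self, marginal, dist):
        # with rho=0 the copula must reproduce the target marginal exactly
        mu = 30.0
        cfg = SimulationConfig(marginal=marginal, rho=0.0)
        rng = np.random.default_rng(3)
        sims = np.array([correlated_counts([mu] * 3, config=cfg, seed=rng)[1]
                         for _ in range(5000)])
        direct = dist(mu).rvs(size=5000, random_state=4)
        assert stats.ks_2samp(sims, direct).pvalue > 0.001

    def test_zip_zero_fraction_at_least_inflation(self):
        cfg = SimulationConfig(marginal="zip", rho=0.0)
        rng = np.random.default_rng(5)
        draws = correlated_counts([10.0] * 4000, config=cfg, seed=rng)
        assert np.mean(draws == 0) >= 0.3 - 0.02

    def test_copula_transform_is_monotone(self):
        cfg = SimulationConfig()
        u = np.linspace(0.001, 0.999, 500)
        for marginal in ("nb", "poisson", "zip"):
            c = SimulationConfig(marginal=marginal)
            vals = _marginal_ppf(u, np.full_like(u, 25.0), c)
            assert np.all(np.diff(vals) >= 0)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            correlated_counts([10.0, 0.0], config=SimulationConfig(), seed=0)


class TestMakeDataset:
    def test_consistent_design_shape_and_truth(self):
        cfg = SimulationConfig(n_da_features=3, n_null_features=2, rng_seed=0)
        ds = make_dataset(cfg)
        assert ds.table.n == 2 * 15 * 21
        assert ds.table.m == 5
        assert ds.sample_masks is None
        da_mask = ds.truth["da_0001"]
        assert da_mask.sum() == 14 and len(da_mask) == 19
        assert not ds.truth["null_0001"].any()
        # DA intervals are exactly the unit intervals inside the DA regions
        starts = np.arange(1, 20)[da_mask]
        for s in starts:
            assert any(a - 1e-9 <= s and s + 1 <= b + 1e-9
                       for a, b in DA_REGIONS)

    def test_inconsistent_design_subject_and_sample_counts(self):
        cfg = SimulationConfig(n_da_features=2, n_null_features=1,
                               design="inconsistent", rng_seed=1)
        ds = make_dataset(cfg)
        for fid in ds.table.feature_ids:
            meta = ds.meta_for_feature(fid)
            a = [m for m in meta if m.group == "A"]
            b = [m for m in meta if m.group == "B"]
            assert len(a) == 8 * 11 and len({m.subject_id for m in a}) == 8
            assert len(b) == 6 * 8 and len({m.subject_id for m in b}) == 6
            per_subj = {}
            for m in a:
                per_subj.setdefault(m.subject_id, []).append(m.time)
            assert all(len(v) == 11 == len(set(v)) for v in per_subj.values())

    def test_same_seed_reproduces_dataset(self):
        cfg = SimulationConfig(n_da_features=2, n_null_features=2,
                               design="inconsistent", rng_seed=7)
        d1, d2 = make_dataset(cfg), make_dataset(cfg)
        np.testing.assert_array_equal(d1.table.counts, d2.table.counts)
        for fid in d1.sample_masks:
            np.testing.assert_array_equal(d1.sample_masks[fid],
                                          d2.sample_masks[fid])

    def test_frozen_design_shares_one_mask(self):
        cfg = SimulationConfig(n_da_features=3, n_null_features=0,
                               design="inconsistent", freeze_design=True,
                               rng_seed=2)
        ds = make_dataset(cfg)
        masks = list(ds.sample_masks.values())
        assert all(np.array_equal(masks[0], m) for m in masks[1:])


def fake_result(feature_id, called_starts, n_intervals=19):
    intervals = []
    for s in range(1, n_intervals + 1):
        sig = s in called_starts
        intervals.append(IntervalResult(feature_id, float(s), float(s + 1),
                                        1.0, 1.0, 0.1, 0.5, 0.5,
                                        "A" if sig else None, sig, True))
    return FeatureTestResult(feature_id, ("A", "B"), intervals, [])


class TestScoreDetector:
    def test_direct_arithmetic_on_confusion_counts(self):
        truth = {"f": np.r_[np.ones(10, bool), np.zeros(9, bool)]}
        # call 9 of the 10 positives (miss one) and 2 of the 9 negatives
        res = {"f": fake_result("f", set(range(1, 10)) | {11, 12})}
        rep = score_detector(res, truth)
        row = rep.per_feature.iloc[0]
        assert (row.tp, row.fn, row.fp, row.tn) == (9, 1, 2, 7)
        assert row.sensitivity == pytest.approx(0.9)
        assert row.specificity == pytest.approx(7 / 9)

    def test_perfect_and_empty_calls(self):
        truth = {"f": np.r_[np.ones(5, bool), np.zeros(14, bool)]}
        perfect = score_detector({"f": fake_result("f", {1, 2, 3, 4, 5})},
                                 truth)
        assert perfect.mean_sensitivity == 1.0
        assert perfect.mean_specificity == 1.0
        silent = score_detector({"f": fake_result("f", set())}, truth)
        assert silent.mean_sensitivity == 0.0
        assert silent.mean_specificity == 1.0

    def test_untestable_feature_counts_as_no_calls(self):
        truth = {"f": np.r_[np.ones(5, bool), np.zeros(14, bool)]}
        res = {"f": FeatureTestResult("f", ("A", "B"), [], [],
                                      untestable_reason="degenerate")}
        rep = score_detector(res, truth)
        assert rep.n_untestable == 1
        assert rep.mean_sensitivity == 0.0

    def test_misaligned_interval_rejected(self):
        truth = {"f": np.zeros(19, bool)}
        bad = fake_result("f", set())
        bad.intervals[0].start = 1.37
        bad.intervals[0].end = 2.37
        with pytest.raises(ValueError, match="unit-interval truth grid"):
            score_detector({"f": bad}, truth)

    def test_missing_feature_rejected(self):
        with pytest.raises(ValueError, match="no test result"):
            score_detector({}, {"f": np.zeros(19, bool)})
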