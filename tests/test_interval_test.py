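import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from longinterval.core_data import SampleMetadata
from longinterval.interval_test import (
    TestConfig, TimeGrid, adjust_bh, area_ratio, area_under_curve,
    build_time_grid, interval_areas, interval_pvalues, permutation_null,
    run_feature_test,
)
from longinterval.nb_spline import LowessFit, SmootherConfig, fit_nb_spline

from conftest import longitudinal_series, make_series


def meta_from_times(times_a, times_b):
    meta = []
    for i, t in enumerate(times_a):
        meta.append(SampleMetadata(f"a{i}", f"subjA{i % 3}", "A", float(t)))
    for i, t in enumerate(times_b):
        meta.append(SampleMetadata(f"b{i}", f"subjB{i % 3}", "B", float(t)))
    return meta


class TestBuildTimeGrid:
    def test_overlap_is_latest_start_to_earliest_end(self):
        # one group observed on days 41..1162, the other 96..1105: intervals
        # can only be tested on 96..1105 where both cohorts have samples
        meta = meta_from_times([41, 500, 1162], [96, 700, 1105])
        grid = build_time_grid(meta, n_points=50)
        assert grid.overlap_range == (96.0, 1105.0)
        assert grid.points[0] == 96.0 and grid.points[-1] == 1105.0

    def test_identical_spans(self):
        meta = meta_from_times([0, 10, 20], [0, 5, 20])
        grid = build_time_grid(meta)
        assert grid.overlap_range == (0.0, 20.0)

    def test_integer_times_get_unit_spacing(self):
        meta = meta_from_times([0, 3, 8], [1, 5, 7])
        grid = build_time_grid(meta)
        np.testing.assert_array_equal(grid.points, np.arange(1.0, 8.0))

    def test_fractional_times_get_twenty_points(self):
        meta = meta_from_times([0.5, 3.25, 8.0], [1.0, 5.0, 7.75])
        grid = build_time_grid(meta)
        assert len(grid.points) == 20

    def test_disjoint_spans_error(self):
        meta = meta_from_times([0, 1, 2], [5, 6, 7])
        with pytest.raises(ValueError, match="do not overlap"):
            build_time_grid(meta)


def linear_curve(slope=1.0, intercept=0.0, lo=0.0, hi=20.0):
    t = np.linspace(lo, hi, 201)
    return LowessFit("A", t, np.maximum(slope * t + intercept, 1e-12),
                     (lo, hi))


class TestAreaUnderCurve:
    def test_constant_curve_rectangle(self):
        fit = linear_curve(0.0, 2.0)
        assert area_under_curve(fit, 3.0, 4.0) == pytest.approx(2.0)

    def test_linear_curve_closed_form(self):
        fit = linear_curve(1.0, 0.0)
        assert area_under_curve(fit, 0.0, 2.0) == pytest.approx(2.0, rel=1e-9)

    def test_spline_area_matches_dense_trapezoid_oracle(self):
        rng = np.random.default_rng(8)
        s = longitudinal_series(rng, lambda t: 20 + 10 * np.sin(np.pi * t / 10),
                                n_subjects=6)
        fit = fit_nb_spline(s, "A")
        for t0, t1 in [(0.0, 1.0), (7.0, 8.0), (13.5, 14.5)]:
            xs = np.linspace(t0, t1, 2001)
            oracle = np.trapezoid(fit.predict_mean(xs), xs)
            got = area_under_curve(fit, t0, t1)
            assert got == pytest.approx(oracle, rel=1e-6)

    def test_out_of_range_refused(self):
        fit = linear_curve(1.0, 0.0, lo=2.0)
        with pytest.raises(ValueError, match="outside"):
            area_under_curve(fit, 0.0, 3.0)

    def test_interval_areas_match_scalar_calls(self):
        rng = np.random.default_rng(9)
        s = longitudinal_series(rng, lambda t: 25 + 5 * np.cos(t / 3),
                                n_subjects=5)
        fit = fit_nb_spline(s, "A")
        grid = TimeGrid(np.arange(0.0, 21.0), (0.0, 20.0))
        vec = interval_areas(fit, grid)
        scalar = [area_under_curve(fit, a, b) for a, b in grid.intervals]
        np.testing.assert_allclose(vec, scalar, rtol=1e-12)


class TestAreaRatio:
    def test_equal_areas_give_zero(self):
        assert area_ratio(3.0, 3.0) == 0.0

    def test_direct_arithmetic(self):
        assert area_ratio(3.0, 1.0) == pytest.approx(2.0 / 3.0)
        assert area_ratio(1.0, 3.0) == pytest.approx(-2.0 / 3.0)

    def test_both_zero_marks_untestable(self):
        assert np.isnan(area_ratio(0.0, 0.0))

    @given(a=st.floats(0.0, 1e6), b=st.floats(0.0, 1e6),
           c=st.floats(1e-6, 1e6))
    @settings(max_examples=200, derandomize=True)
    def test_bounds_antisymmetry_scale_invariance(self, a, b, c):
        if max(a, b) == 0:
            return
        ar = area_ratio(a, b)
        assert -1.0 <= ar <= 1.0
        assert area_ratio(b, a) == pytest.approx(-ar, abs=1e-12)
        assert area_ratio(c * a, c * b) == pytest.approx(ar, rel=1e-9,
                                                         abs=1e-9)


class TestIntervalPvalues:
    def test_observed_beats_all_null_draws(self):
        null = np.abs(np.random.default_rng(0).normal(size=(99, 1))) * 0.1
        p = interval_pvalues(np.array([5.0]), null)
        assert p[0] == pytest.approx(1.0 / 100.0)

    def test_zero_observed_ar_gives_p_one(self):
        null = np.random.default_rng(0).normal(size=(50, 1))
        p = interval_pvalues(np.array([0.0]), null)
        assert p[0] == 1.0

    def test_median_observed_gives_half(self):
        null = np.arange(1.0, 100.0).reshape(99, 1)  # |null| = 1..99
        p = interval_pvalues(np.array([50.0]), null)
        # 50 draws >= 50 -> (1+50)/100
        assert p[0] == pytest.approx(0.51)

    def test_untestable_interval_stays_nan(self):
        null = np.ones((10, 2))
        p = interval_pvalues(np.array([np.nan, 0.5]), null)
        assert np.isnan(p[0]) and np.isfinite(p[1])


class TestAdjustBH:
    def test_single_pvalue_unchanged(self):
        np.testing.assert_allclose(adjust_bh([0.04]), [0.04])

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(adjust_bh([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_ties_stay_equal(self):
        np.testing.assert_allclose(adjust_bh([0.2, 0.2, 0.2]), [0.2] * 3)

    def test_monotone_in_raw_pvalues_and_at_least_raw(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=40)
        q = adjust_bh(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= p - 1e-12)


def two_group_series(rng, n_subj=5, identical=False, mu_b=20.0):
    times = np.arange(11.0)
    t_all, y_all, g_all, s_all = [], [], [], []
    for g, mu in (("A", 30.0), ("B", 30.0 if identical else mu_b)):
        for i in range(n_subj):
            y = rng.poisson(mu, size=len(times))
            t_all.append(times)
            y_all.append(y)
            g_all.extend([g] * len(times))
            s_all.extend([f"{g}{i}"] * len(times))
    return make_series(np.concatenate(t_all), np.concatenate(y_all),
                       g_all, s_all)


class TestPermutationNull:
    def test_null_symmetric_under_exchangeability(self):
        rng = np.random.default_rng(2)
        s = two_group_series(rng, identical=True)
        grid = TimeGrid(np.arange(0.0, 11.0), (0.0, 10.0))
        null, _ = permutation_null(
            s, grid, TestConfig(n_permutations=200, rng_seed=5),
            SmootherConfig(fixed_lambda=1.0))
        draws = null[np.isfinite(null)]
        n_pos = np.sum(draws > 0)
        n = np.sum(draws != 0)
        from scipy.stats import binomtest
        assert binomtest(int(n_pos), int(n)).pvalue > 0.01

    def test_single_permutation_single_draw(self):
        rng = np.random.default_rng(3)
        s = two_group_series(rng)
        grid = TimeGrid(np.arange(0.0, 11.0), (0.0, 10.0))
        null, failures = permutation_null(
            s, grid, TestConfig(n_permutations=1, rng_seed=1),
            SmootherConfig(fixed_lambda=1.0))
        assert null.shape == (1, grid.n_intervals)

    def test_fixed_seed_bit_identical(self):
        rng = np.random.default_rng(4)
        s = two_group_series(rng)
        grid = TimeGrid(np.arange(0.0, 11.0), (0.0, 10.0))
        cfg = TestConfig(n_permutations=25, rng_seed=11)
        sm = SmootherConfig(fixed_lambda=1.0)
        n1, _ = permutation_null(s, grid, cfg, sm)
        n2, _ = permutation_null(s, grid, cfg, sm)
        np.testing.assert_array_equal(n1, n2)


class TestRunFeatureTest:
    def test_identical_groups_find_nothing(self):
        rng = np.random.default_rng(5)
        s = two_group_series(rng, identical=True)
        grid = TimeGrid(np.arange(0.0, 11.0), (0.0, 10.0))
        res = run_features = run_feature_test(
            s, grid, TestConfig(n_permutations=100, rng_seed=0))
        assert res.testable
        assert not any(r.significant for r in res.intervals)

    def test_group_relabeling_flips_ar_sign(self):
        rng = np.random.default_rng(6)
        s = two_group_series(rng, mu_b=10.0)
        swapped = make_series(
            s.times, s.counts,
            ["B" if g == "A" else "A" for g in s.groups], list(s.subjects))
        grid = TimeGrid(np.arange(0.0, 11.0), (0.0, 10.0))
        cfg = TestConfig(n_permutations=50, rng_seed=3)
        r1 = run_feature_test(s, grid, cfg)
        r2 = run_feature_test(swapped, grid, cfg)
        ar1 = [r.ar for r in r1.intervals]
        ar2 = [r.ar for r in r2.intervals]
        np.testing.assert_allclose(ar1, [-a for a in ar2], rtol=1e-9)

    def test_strong_signal_found_and_merged(self):
        rng = np.random.default_rng(7)
        s = two_group_series(rng, mu_b=5.0)
        grid = TimeGrid(np.arange(0.0, 11.0), (0.0, 10.0))
        res = run_feature_test(s, grid,
                               TestConfig(n_permutations=200, rng_seed=2))
        assert all(r.significant for r in res.intervals)
        assert res.merged == [(0.0, 10.0, "A")]
        for r in res.intervals:
            assert r.adjusted_pvalue >= r.pvalue - 1e-12
            assert r.dominant_group == "A" and r.ar > 0

    def test_no_interval_outside_overlap_range(self):
        rng = np.random.default_rng(8)
        s = two_group_series(rng, mu_b=5.0)
        grid = build_time_grid(
            meta_from_times([0, 4, 8, 10], [2, 5, 10]))
        assert grid.overlap_range == (2.0, 10.0)
        res_grid_points = grid.points
        assert res_grid_points[0] >= 2.0 and res_grid_points[-1] <= 10.0
        res = run_feature_test(s, grid,
                               TestConfig(n_permutations=20, rng_seed=1))
        for r in res.intervals:
            assert r.start >= 2.0 - 1e-9 and r.end <= 10.0 + 1e-9
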