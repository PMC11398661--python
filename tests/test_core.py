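"""Tests for the truncated time-shift engine: windows, counts, the u
statistic, radius selection, lagging, the detrend-retrend variant and BH
adjustment."""

import numpy as np
import pytest

from ttshift import (
    LargeRadiusWarning,
    Series,
    bh_adjust,
    count_B,
    default_radius,
    detrend_retrend_tts,
    lag_preshift,
    make_statistic,
    multi_lag_tts,
    naive_p,
    optimal_radius,
    pearson_strength,
    polynomial_trend,
    shift_profile,
    shifted_window,
    truncate,
    tts_test,
    u_statistic,
)
from ttshift.core import ShiftProfile
from ttshift.errors import (
    ConfigError,
    InsufficientDataError,
    InvalidLagError,
    InvalidRadiusError,
    InvalidShiftError,
    TTSError,
)
from ttshift.statistics import HIGHER_STRONGER, LOWER_STRONGER, StatisticSpec
from ttshift.systems import simulate_ar1

PEARSON = make_statistic("pearson")

# a Pearson spec under a different name: forces the generic (loop) profile
# path, so fast and generic paths can be compared
PEARSON_LOOP = StatisticSpec(
    "pearson-loop", lambda a, b: pearson_strength(a.as_1d(), b.as_1d())
)


class TestWindows:
    def test_truncate(self):
        assert truncate(Series([1, 2, 3, 4]), 1).as_1d().tolist() == [2, 3]
        assert truncate(Series([1, 2, 3, 4]), 0).as_1d().tolist() == [1, 2, 3, 4]
        assert truncate(Series([1, 2, 3, 4, 5]), 2).as_1d().tolist() == [3]

    def test_truncate_preserves_features(self):
        s = Series(np.arange(12).reshape(2, 6), feature_ids=("a", "b"))
        out = truncate(s, 2)
        assert out.n_features == 2 and out.feature_ids == ("a", "b")

    def test_truncate_invalid_radius(self):
        with pytest.raises(InvalidRadiusError):
            truncate(Series([1, 2, 3, 4]), 2)
        with pytest.raises(InvalidRadiusError):
            truncate(Series([1, 2, 3]), -1)

    @pytest.mark.parametrize(
        "delta,expected", [(0, [2, 3]), (1, [3, 4]), (-1, [1, 2])]
    )
    def test_shifted_window(self, delta, expected):
        assert shifted_window(Series([1, 2, 3, 4]), 1, delta).as_1d().tolist() == expected

    def test_shifted_window_invalid(self):
        with pytest.raises(InvalidShiftError):
            shifted_window(Series([1, 2, 3, 4]), 1, 2)

    def test_lag_preshift(self):
        x = Series(np.arange(1, 7), label="x")
        y = Series(np.arange(11, 17), label="y")
        xl, yl = lag_preshift(x, y, 0)
        assert xl is x and yl is y
        xl, yl = lag_preshift(x, y, 2)
        assert xl.as_1d().tolist() == [3, 4, 5, 6]
        assert yl.as_1d().tolist() == [11, 12, 13, 14]
        xl, yl = lag_preshift(x, y, -2)
        assert xl.as_1d().tolist() == [1, 2, 3, 4]
        assert yl.as_1d().tolist() == [13, 14, 15, 16]
        with pytest.raises(InvalidLagError):
            lag_preshift(x, y, 6)

    def test_lag_preshift_involution_on_swap(self):
        """lag_preshift(l) then lag_preshift(-l) on the swapped pair returns
        the overlapping index set."""
        x = Series(np.arange(10.0))
        y = Series(np.arange(10.0, 20.0))
        xl, yl = lag_preshift(x, y, 3)
        yb, xb = lag_preshift(yl, xl, -3)
        # the composition restricts both series to the overlapping index set
        assert xb.n == yb.n == 10 - 2 * 3
        assert np.all(np.isin(xb.as_1d(), xl.as_1d()))
        assert np.all(np.isin(yb.as_1d(), yl.as_1d()))


class TestProfileAndCounts:
    def test_self_profile_theta0_is_one(self, rng):
        s = Series(rng.normal(size=60))
        prof = shift_profile(s, s, 4, PEARSON)
        assert prof.theta0 == pytest.approx(1.0)
        assert len(prof.theta) == 9

    def test_zero_radius_profile(self, rng):
        a = Series(rng.normal(size=30))
        b = Series(rng.normal(size=30))
        prof = shift_profile(a, b, 0, PEARSON)
        assert prof.theta.shape == (1,)
        assert prof.theta0 == pytest.approx(pearson_strength(a.as_1d(), b.as_1d()))

    def test_profile_matches_independent_loop(self):
        """Fast vectorized profile equals a from-scratch loop over shifts."""
        x = simulate_ar1(80, phi=0.6, seed=1)
        y = simulate_ar1(80, phi=0.6, seed=2)
        r = 3
        prof = shift_profile(x, y, r, PEARSON)
        xv, yv = x.as_1d(), y.as_1d()
        n = 80
        for i, delta in enumerate(range(-r, r + 1)):
            a = xv[r : n - r]
            b = yv[r + delta : n - r + delta]
            expected = abs(np.corrcoef(a, b)[0, 1])
            assert prof.theta[i] == pytest.approx(expected, rel=1e-12)

    def test_fast_and_generic_paths_agree(self, rng):
        x = Series(rng.normal(size=100))
        y = Series(rng.normal(size=100))
        fast = shift_profile(x, y, 5, PEARSON)
        slow = shift_profile(x, y, 5, PEARSON_LOOP)
        np.testing.assert_allclose(fast.theta, slow.theta, rtol=1e-12)

    def test_shift_x_instead_of_y(self, rng):
        x = Series(rng.normal(size=100))
        y = Series(rng.normal(size=100))
        prof = shift_profile(x, y, 4, PEARSON, shift="x")
        xv, yv = x.as_1d(), y.as_1d()
        for i, delta in enumerate(range(-4, 5)):
            expected = pearson_strength(xv[4 + delta : 96 + delta], yv[4:96])
            assert prof.theta[i] == pytest.approx(expected, rel=1e-12)

    def test_degenerate_window_names_shift(self):
        x = Series(np.r_[np.zeros(5), 1.0, np.zeros(5)])
        y = Series(np.r_[np.arange(6.0), np.zeros(5)])
        # at some shift the y window is constant -> error mentions delta
        with pytest.raises(TTSError, match="delta"):
            shift_profile(y, x, 4, PEARSON_LOOP)

    def test_count_B_strict_maximum(self):
        prof = ShiftProfile(r=1, theta=np.array([0.1, 0.9, 0.2]),
                            orientation=HIGHER_STRONGER)
        assert count_B(prof) == 1

    def test_count_B_total_tie(self):
        prof = ShiftProfile(r=2, theta=np.full(5, 0.3), orientation=HIGHER_STRONGER)
        assert count_B(prof) == 5

    def test_count_B_lower_stronger(self):
        prof = ShiftProfile(r=1, theta=np.array([0.5, 0.2, 0.3]),
                            orientation=LOWER_STRONGER)
        assert count_B(prof) == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_count_B_matches_double_loop(self, seed):
        """count_B + shift_profile vs a naive independent double loop."""
        rng = np.random.default_rng(seed)
        r = int(rng.integers(1, 6))
        n = int(rng.integers(2 * r + 5, 40))
        x = Series(rng.normal(size=n))
        y = Series(rng.normal(size=n))
        prof = shift_profile(x, y, r, PEARSON)
        # oracle: recompute every correlation then count >= theta0
        xv, yv = x.as_1d(), y.as_1d()
        theta0 = pearson_strength(xv[r : n - r], yv[r : n - r])
        count = 0
        for delta in range(-r, r + 1):
            th = pearson_strength(xv[r : n - r], yv[r + delta : n - r + delta])
            if th >= theta0:
                count += 1
        assert count_B(prof) == count


class TestUStatistic:
    def test_printed_values(self):
        assert u_statistic(1, 19) == pytest.approx(0.05)
        assert u_statistic(2, 38) == pytest.approx(2 / 39)
        assert u_statistic(3, 1) == pytest.approx(1.5)

    def test_naive_values(self):
        assert naive_p(1, 19) == pytest.approx(1 / 39)
        for r in (1, 5, 19):
            assert naive_p(2 * r + 1, r) == 1.0

    def test_domain_errors(self):
        for fn in (u_statistic, naive_p):
            with pytest.raises(TTSError):
                fn(0, 5)
            with pytest.raises(TTSError):
                fn(12, 5)

    def test_ratio_strictly_below_two(self):
        """u / p_naive = (2r+1)/(r+1) < 2 for every admissible (B, r)."""
        r = np.arange(1, 10_001)
        ratio = (2 * r + 1) / (r + 1)
        assert ratio.max() < 2.0
        assert ratio.min() >= 1.5
        # spot-check that the identity really is B-independent
        for B in (1, 3, 7):
            assert u_statistic(B, 10) / naive_p(B, 10) == pytest.approx(21 / 11)


class TestTTSTest:
    def test_self_pair(self, rng):
        s = Series(rng.normal(size=120))
        for r in (3, 10):
            res = tts_test(s, s, r, PEARSON)
            assert res.B == 1
            assert res.u == pytest.approx(1 / (r + 1))
            assert res.p_reported == min(res.u, 1.0)

    def test_deterministic(self, gaussian_pair):
        x, y = gaussian_pair
        r1 = tts_test(x, y, 19, PEARSON)
        r2 = tts_test(x, y, 19, PEARSON)
        assert r1.B == r2.B and r1.u == r2.u and r1.reject == r2.reject
        np.testing.assert_array_equal(r1.profile.theta, r2.profile.theta)

    def test_reject_rule(self, gaussian_pair):
        x, y = gaussian_pair
        res = tts_test(x, y, 19, PEARSON, alpha=0.05)
        assert res.reject == (res.u <= 0.05)
        assert 1 <= res.B <= 2 * 19 + 1

    def test_refuses_missing_values(self):
        x = Series([1.0, np.nan, 3.0, 4.0, 5.0, 6.0, 7.0])
        y = Series(np.arange(7.0))
        with pytest.raises(ValueError, match="missing"):
            tts_test(x, y, 1, PEARSON)

    def test_large_radius_warning(self, rng):
        x = Series(rng.normal(size=60))
        y = Series(rng.normal(size=60))
        with pytest.warns(LargeRadiusWarning):
            tts_test(x, y, 25, PEARSON)

    def test_null_calibration_iid(self):
        """P(u <= alpha) <= alpha for independent iid Gaussian pairs."""
        trials = 2000
        alpha = 0.05
        rng = np.random.default_rng(42)
        rejections = 0
        for _ in range(trials):
            x = Series(rng.normal(size=200))
            y = Series(rng.normal(size=200))
            rejections += tts_test(x, y, 19, PEARSON, alpha=alpha).reject
        margin = 3 * np.sqrt(alpha * (1 - alpha) / trials)
        assert rejections / trials <= alpha + margin

    def test_probability_B_equals_one(self):
        """Under exchangeability with a continuous statistic,
        P(B = 1) is close to 1/(2r+1)."""
        trials = 2000
        r = 4
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(trials):
            x = Series(rng.normal(size=60))
            y = Series(rng.normal(size=60))
            hits += tts_test(x, y, r, PEARSON).B == 1
        expect = 1 / (2 * r + 1)
        se = np.sqrt(expect * (1 - expect) / trials)
        assert abs(hits / trials - expect) < 4 * se


class TestMultiLag:
    def test_single_lag_reduces_to_tts(self, gaussian_pair):
        x, y = gaussian_pair
        multi = multi_lag_tts(x, y, 19, PEARSON, lags=[0], alpha=0.05)
        single = tts_test(x, y, 19, PEARSON, alpha=0.05)
        assert multi.reject == single.reject
        assert multi.per_lag[0].u == single.u

    def test_bonferroni_threshold(self, gaussian_pair):
        x, y = gaussian_pair
        res = multi_lag_tts(x, y, 19, PEARSON, lags=[0, 1, 2, 3, 4], alpha=0.05)
        assert all(t.alpha == pytest.approx(0.01) for t in res.per_lag)
        assert res.reject == any(t.u <= 0.01 for t in res.per_lag)

    def test_duplicate_lags_rejected(self, gaussian_pair):
        x, y = gaussian_pair
        with pytest.raises(ConfigError):
            multi_lag_tts(x, y, 19, PEARSON, lags=[0, 1, 1])

    def test_null_calibration(self):
        """Bonferroni multi-lag keeps the family FPR at or below alpha."""
        trials = 1000
        alpha = 0.05
        rng = np.random.default_rng(99)
        rejections = 0
        for _ in range(trials):
            x = Series(rng.normal(size=300))
            y = Series(rng.normal(size=300))
            res = multi_lag_tts(x, y, 99, PEARSON, lags=[0, 1, 2, 3, 4], alpha=alpha)
            rejections += res.reject
        margin = 3 * np.sqrt(alpha * (1 - alpha) / trials)
        assert rejections / trials <= alpha + margin


class TestRadiusSelection:
    def test_optimal_radius_printed_values(self):
        assert optimal_radius(0.05, m=1, j=1) == 19
        assert optimal_radius(0.05, m=5, j=1) == 99
        assert optimal_radius(0.01, m=1, j=2) == 199

    def test_optimal_radius_rounding_flag(self):
        with pytest.warns(UserWarning, match="rounding"):
            r = optimal_radius(0.03, m=1, j=1)  # 1/0.03 not an integer
        assert r == 32

    def test_optimal_radius_domain(self):
        with pytest.raises(TTSError):
            optimal_radius(0.0)
        with pytest.raises(TTSError):
            optimal_radius(1.5)

    def test_default_radius(self):
        assert default_radius(400, 0.05, 1) == 79
        assert default_radius(100, 0.05, 1) == 19
        with pytest.raises(InsufficientDataError, match="199"):
            default_radius(50, 0.05, 5)

    def test_default_radius_short_series_falls_back_to_minimum(self):
        # n/5 below the j=1 lattice point, but series still long enough
        assert default_radius(45, 0.05, 1) == 19


class TestDetrendRetrend:
    def test_zero_trend_reduces_to_plain_test(self, rng):
        x = Series(rng.normal(size=150))
        y = Series(rng.normal(size=150))
        plain = tts_test(x, y, 10, PEARSON)
        zero = detrend_retrend_tts(
            x, y, 10, PEARSON, trend_fitter=lambda s: np.zeros_like(s.values)
        )
        np.testing.assert_allclose(zero.profile.theta, plain.profile.theta, rtol=1e-9)
        assert zero.B == plain.B

    def test_unshifted_surrogate_is_original(self, rng):
        """theta at delta = 0 equals the statistic on the original pair."""
        t = np.arange(150.0)
        x = Series(rng.normal(size=150))
        y = Series(0.03 * t + rng.normal(size=150))
        res = detrend_retrend_tts(x, y, 10, PEARSON)
        direct = pearson_strength(x.as_1d()[10:140], y.as_1d()[10:140])
        assert res.profile.theta0 == pytest.approx(direct, rel=1e-12)

    def test_generic_path_matches_fast_path(self, rng):
        t = np.arange(120.0)
        x = Series(rng.normal(size=120))
        y = Series(0.05 * t + rng.normal(size=120))
        fast = detrend_retrend_tts(x, y, 8, PEARSON)
        slow = detrend_retrend_tts(x, y, 8, PEARSON_LOOP)
        np.testing.assert_allclose(fast.profile.theta, slow.profile.theta, rtol=1e-10)
        assert fast.B == slow.B

    def test_null_calibration_on_trended_ar1(self):
        """Detrend-retrend controls the FPR on AR(1) plus a linear trend."""
        from ttshift.benchmark import ExperimentConfig, run_fpr_experiment

        cfg = ExperimentConfig(
            system="trended_ar1", n=500, test="detrend_tts", statistic="pearson",
            n_trials=2000, alpha=0.05, master_seed=202, test_params={"r": 19},
        )
        res = run_fpr_experiment(cfg)
        margin = 3 * np.sqrt(0.05 * 0.95 / res.n_trials)
        assert res.rate <= 0.05 + margin

    def test_trend_fitter_recovers_linear_slope(self, rng):
        t = np.arange(500.0)
        y = Series(0.01 * t + rng.normal(size=500))
        trend = polynomial_trend(1)(y)
        slope = (trend[0, -1] - trend[0, 0]) / 499
        assert slope == pytest.approx(0.01, abs=0.002)


class TestBHAdjust:
    def test_examples(self):
        np.testing.assert_allclose(bh_adjust([0.05]), [0.05])
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_hand_computed_stepup(self):
        # sorted p * n/i, running min from the top, restored to input order
        p = [0.005, 0.04, 0.03, 0.1]
        expected = [0.02, 0.053333333333333337, 0.053333333333333337, 0.1]
        np.testing.assert_allclose(bh_adjust(p), expected)

    def test_superuniform_inputs_clipped(self):
        out = bh_adjust([1.4, 0.02])  # u statistics can exceed 1
        assert out[0] == 1.0
        assert bh_adjust([]).size == 0
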