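"""Tests for block averaging, extrapolation and time-series diagnostics."""

import numpy as np
import pytest

from entroconv import (
    ConvergenceCurve,
    EnergySeries,
    GaussianSpec,
    StreamSpec,
    analytic_c2,
    autocorrelation,
    block_estimates,
    convergence_curve,
    extrapolate,
    gaussian_stream,
    gaussianity_report,
    generate,
    ie_entropy,
    running_average,
    statistical_inefficiency,
)
from entroconv.constants import R_KJ_MOL_K

RT300 = R_KJ_MOL_K * 300.0


class TestBlockEstimates:
    def test_alternating_series_closed_form(self, toy_series):
        # blocks [-1,1] and [-1,1]: each IE value is RT ln cosh(1/RT)
        mean, se, per_block = block_estimates(toy_series, 2, "IE")
        expected = RT300 * np.log(np.cosh(1.0 / RT300))
        np.testing.assert_allclose(per_block, expected, rtol=1e-12)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_identical_blocks_zero_stderr(self):
        s = EnergySeries(np.tile([0.0, 2.0, -2.0], 4))
        _, se, _ = block_estimates(s, 3, "C2")
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_remainder_discarded(self):
        s = EnergySeries(np.arange(10, dtype=float))
        _, _, per_block = block_estimates(s, 3, "C2")
        assert per_block.size == 3  # 10 // 3

    def test_block_size_exceeding_length_rejected(self, toy_series):
        with pytest.raises(ValueError):
            block_estimates(toy_series, 10, "IE")

    def test_ie_blocks_grow_with_n_c2_flat_at_sigma_15(self):
        # the central published diagnostic: on sigma=15 Gaussian data the
        # IE block-mean climbs with block size while C2 stays flat
        s = gaussian_stream(GaussianSpec(15.0), 400_000, seed=9)
        ie_small, _, _ = block_estimates(s, 1000, "IE")
        ie_large, _, _ = block_estimates(s, 100_000, "IE")
        assert ie_large > ie_small + 2.0
        c2_small, se_s, _ = block_estimates(s, 1000, "C2")
        c2_large, se_l, _ = block_estimates(s, 100_000, "C2")
        assert abs(c2_large - c2_small) < 2.0


class TestConvergenceCurve:
    def test_single_block_size(self, toy_series):
        curve = convergence_curve(toy_series, [2], "IE")
        assert len(curve.points) == 1

    def test_constant_series_flat_at_zero(self):
        s = EnergySeries(np.full(100, 5.0))
        curve = convergence_curve(s, [2, 10, 50], "IE")
        np.testing.assert_allclose(curve.estimates, 0.0, atol=1e-12)

    def test_c2_flat_at_analytic_level(self):
        s = gaussian_stream(GaussianSpec(13.0), 200_000, seed=12)
        curve = convergence_curve(s, [100, 1000, 10_000], "C2")
        level = analytic_c2(GaussianSpec(13.0))
        for n, est, se, nb in curve.points:
            assert est == pytest.approx(level, abs=max(2 * se, 0.5))

    def test_strictly_increasing_n_enforced(self):
        with pytest.raises(ValueError):
            ConvergenceCurve([(10, 1.0, None, 1), (10, 1.0, None, 1)], "IE")


class TestRunningAverage:
    def test_final_point_is_whole_series(self):
        s = gaussian_stream(GaussianSpec(5.0), 1000, seed=1)
        curve = running_average(s, "IE", stride=300)
        assert curve.points[-1][0] == 1000
        assert curve.points[-1][1] == pytest.approx(
            ie_entropy(s).minus_T_delta_S, abs=1e-12)

    def test_constant_series_all_zero(self):
        s = EnergySeries(np.full(50, -3.0))
        curve = running_average(s, "IE", stride=10)
        np.testing.assert_allclose(curve.estimates, 0.0, atol=1e-12)

    def test_final_ie_below_analytic_for_sigma_15(self):
        s = gaussian_stream(GaussianSpec(15.0), 100_000, seed=21)
        curve = running_average(s, "IE", stride=100_000)
        assert curve.points[-1][1] < analytic_c2(GaussianSpec(15.0))


class TestExtrapolate:
    @staticmethod
    def _power_curve(s_inf, a, c, noise=0.0, seed=0):
        n = np.array([100, 300, 1000, 3000, 10_000, 30_000])
        rng = np.random.default_rng(seed)
        y = s_inf - a * n ** (-c) + noise * rng.standard_normal(n.size)
        return ConvergenceCurve(
            [(int(k), float(v), None, 1) for k, v in zip(n, y)], "IE")

    def test_exact_recovery(self):
        fit = extrapolate(self._power_curve(50.0, 30.0, 0.25), c=0.25)
        assert fit.s_infinity == pytest.approx(50.0, abs=1e-9)
        assert fit.amplitude == pytest.approx(30.0, abs=1e-6)
        assert fit.residual == pytest.approx(0.0, abs=1e-9)

    def test_flat_curve(self):
        curve = ConvergenceCurve(
            [(100, 12.0, None, 1), (1000, 12.0, None, 1), (10_000, 12.0, None, 1)],
            "C2")
        fit = extrapolate(curve, c=0.25)
        assert fit.s_infinity == pytest.approx(12.0, abs=1e-9)
        assert abs(fit.amplitude) < 1e-6

    def test_wrong_exponent_leaves_residual(self):
        curve = self._power_curve(50.0, 30.0, 0.25)
        good = extrapolate(curve, c=0.25).residual
        bad = extrapolate(curve, c=0.5).residual
        assert bad > good + 1e-3

    def test_noisy_recovery_within_2(self):
        curve = self._power_curve(50.0, 30.0, 0.25, noise=0.5, seed=3)
        fit = extrapolate(curve, c=0.25)
        assert fit.s_infinity == pytest.approx(50.0, abs=2.0)

    def test_too_few_points_rejected(self):
        curve = ConvergenceCurve([(10, 1.0, None, 1), (20, 2.0, None, 1)], "IE")
        with pytest.raises(ValueError):
            extrapolate(curve, c=0.25)


class TestAutocorrelation:
    def test_lag0_exactly_one_and_iid_near_zero(self):
        s = gaussian_stream(GaussianSpec(10.0), 100_000, seed=2)
        rho = autocorrelation(s, 5)
        assert rho[0] == 1.0
        assert abs(rho[1]) <= 3.0 / np.sqrt(len(s))

    def test_ar1_lag1_matches_phi(self):
        # phi=0.74 emulates the published 10-fs sampling correlation
        s = generate(StreamSpec(kind="ar1", sigma=10.0, phi=0.74,
                                n=200_000, seed=8))
        rho = autocorrelation(s, 3)
        assert rho[1] == pytest.approx(0.74, abs=0.02)

    def test_reversal_symmetry(self):
        s = generate(StreamSpec(kind="ar1", sigma=5.0, phi=0.5, n=5000, seed=4))
        fwd = autocorrelation(s, 10)
        rev = autocorrelation(s.with_values(s.values[::-1]), 10)
        np.testing.assert_allclose(fwd, rev, atol=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            autocorrelation(EnergySeries(np.full(100, 1.0)), 5)


class TestStatisticalInefficiency:
    def test_iid_near_one(self):
        s = gaussian_stream(GaussianSpec(10.0), 100_000, seed=6)
        assert statistical_inefficiency(s) <= 1.1

    @pytest.mark.parametrize("phi", [0.5, 0.95])
    def test_ar1_closed_form(self, phi):
        # population value (1+phi)/(1-phi): 3 at phi=0.5 (the buried-site
        # regime), 39 at phi=0.95 (the strongly oversampled regime)
        s = generate(StreamSpec(kind="ar1", sigma=10.0, phi=phi,
                                n=100_000, seed=13))
        expected = (1 + phi) / (1 - phi)
        assert statistical_inefficiency(s) == pytest.approx(expected, rel=0.15)

    def test_duplicated_stream_scales_like_k(self):
        # repeating every energy k times costs a factor ~k in effective
        # samples: the "use each energy 10 times" argument
        k = 10
        s = generate(StreamSpec(kind="duplicated", sigma=10.0, repeat_k=k,
                                n=20_000, seed=5))
        g = statistical_inefficiency(s)
        assert k * 0.7 <= g <= k * 1.4

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            statistical_inefficiency(EnergySeries(np.arange(50, dtype=float)))


class TestGaussianityReport:
    def test_gaussian_sample_near_normal_moments(self):
        s = gaussian_stream(GaussianSpec(12.0), 1_000_000, seed=14)
        rep = gaussianity_report(s)
        assert abs(rep.skewness) <= 0.05
        assert abs(rep.excess_kurtosis) <= 0.1
        assert rep.sigma == pytest.approx(12.0, abs=0.05)

    def test_shifted_exponential_skewness(self):
        rng = np.random.default_rng(15)
        s = EnergySeries(rng.exponential(5.0, 500_000) - 20.0)
        rep = gaussianity_report(s)
        assert rep.skewness == pytest.approx(2.0, abs=0.1)

    def test_mixture_skew_sign_matches_heavy_tail(self):
        s = generate(StreamSpec(
            kind="mixture",
            components=[(0.75, 10.0, 35.0), (0.25, -30.0, 100.0)],
            n=500_000, seed=16))
        rep = gaussianity_report(s)
        assert rep.skewness < -0.1  # heavier low-energy tail

    def test_overlay_integrates_to_one(self):
        s = gaussian_stream(GaussianSpec(8.0), 10_000, seed=17)
        rep = gaussianity_report(s, n_bins=200)
        width = rep.bin_centers[1] - rep.bin_centers[0]
        assert np.sum(rep.normal_density) * width == pytest.approx(1.0, abs=0.02)
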