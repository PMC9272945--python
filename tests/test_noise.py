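"""Rician magnitude statistics, biased fits, thresholds, dot fractions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rice

from srrmri import (
    DotModel,
    MonoExpParams,
    RicianNoiseModel,
    contrast_ratio,
    dot_signal,
    estimate_fdot,
    fit_biased_monoexp,
    monoexp_signal,
    rician_expected_signal,
    sample_magnitude,
    snfr,
    snr,
    threshold_attenuation_from_snfr,
    threshold_b_value,
)
from srrmri.pipelines import default_b_values

FLOOR = np.sqrt(np.pi / 2)


class TestExpectedMagnitude:
    def test_pure_noise_floor(self):
        assert rician_expected_signal(0.0, 1.0) == pytest.approx(FLOOR, rel=1e-12)

    def test_noise_free_limit(self):
        assert rician_expected_signal(3.2, 0.0) == 3.2

    def test_closed_form_value(self):
        assert rician_expected_signal(1.0, 0.5) == pytest.approx(1.1801, abs=1e-4)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            rician_expected_signal(-1.0, 0.5)
        with pytest.raises(ValueError):
            rician_expected_signal(1.0, -0.5)

    @pytest.mark.parametrize("ratio", [1.0, 2.0, 3.0, 5.0, 10.0])
    def test_within_five_percent_of_rice_mean_above_unit_snr(self, ratio):
        """The closed form interpolates the exact Rice mean to <5% for
        SNR >= 1 (it overshoots most around SNR ~ 1-2)."""
        sigma = 0.7
        s = ratio * sigma
        exact = rice.mean(s / sigma, scale=sigma)
        approx = rician_expected_signal(s, sigma)
        assert abs(approx / exact - 1) < 0.05

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        s=st.floats(0.0, 10.0, allow_nan=False),
        sigma=st.floats(0.0, 2.0, allow_nan=False),
    )
    def test_expected_magnitude_bounds(self, s, sigma):
        """The expected magnitude lies between the noiseless signal/floor
        and their sum, and is monotone in both arguments."""
        m = rician_expected_signal(s, sigma)
        floor = sigma * FLOOR
        assert m >= max(s, floor) - 1e-12
        assert m <= s + floor + 1e-12
        assert rician_expected_signal(s + 0.5, sigma) >= m
        assert rician_expected_signal(s, sigma + 0.5) >= m

    def test_monte_carlo_cross_check(self):
        """Large-sample mean of rectified complex draws sits between the
        exact Rice mean and the closed-form value (which overshoots a
        few percent at SNR = 2)."""
        model = RicianNoiseModel(sigma=0.5)
        draws = sample_magnitude(1.0, model, n_draws=10 ** 6, seed=11)
        assert draws.mean() == pytest.approx(rice.mean(2.0, scale=0.5), rel=2e-3)
        assert abs(rician_expected_signal(1.0, 0.5) / draws.mean() - 1) < 0.05


class TestMagnitudeSampling:
    def test_zero_noise_returns_signal(self):
        model = RicianNoiseModel(sigma=0.0)
        np.testing.assert_array_equal(sample_magnitude(2.5, model, 10, seed=0), 2.5)

    def test_seed_determinism(self):
        model = RicianNoiseModel(sigma=0.014)
        a = sample_magnitude(1.0, model, 100, seed=42)
        b = sample_magnitude(1.0, model, 100, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_rayleigh_mean_at_zero_signal(self):
        sigma = 0.014
        draws = sample_magnitude(0.0, RicianNoiseModel(sigma), 10 ** 4, seed=3)
        se = sigma * np.sqrt(2 - np.pi / 2) / 100
        assert abs(draws.mean() - sigma * FLOOR) < 3 * se

    def test_negligible_bias_at_high_snr(self):
        draws = sample_magnitude(1.0, RicianNoiseModel(0.014), 10 ** 4, seed=4)
        assert abs(draws.mean() - 1.0) < 1e-3

    def test_invalid_draw_count(self):
        with pytest.raises(ValueError):
            sample_magnitude(1.0, RicianNoiseModel(0.1), n_draws=0)


class TestSnrAndSnfr:
    def test_definitions_and_fixed_ratio(self):
        assert snr(1.0, 0.014) == pytest.approx(71.43, abs=0.01)
        assert snr(6.0, 0.014) == pytest.approx(428.6, abs=0.1)
        assert snfr(2.0, 0.1) / snr(2.0, 0.1) == pytest.approx(1 / FLOOR, rel=1e-12)

    def test_snfr_scales_linearly_with_voxel_volume(self):
        base = snfr(1.0 * 1.0, 0.014)
        assert snfr(1.0 * 2.0, 0.014) == pytest.approx(2 * base, rel=1e-12)

    def test_zero_sigma_is_undefined(self):
        with pytest.raises(ZeroDivisionError):
            snr(1.0, 0.0)
        with pytest.raises(ZeroDivisionError):
            snfr(1.0, 0.0)


class TestMonoExp:
    def test_signal_values(self):
        p = MonoExpParams(s0=1.0, diffusivity=2.2, aspect_factor=1.0)
        assert monoexp_signal(p, 0.0) == 1.0
        assert monoexp_signal(p, 1.0) == pytest.approx(np.exp(-2.2), rel=1e-12)
        p6 = MonoExpParams(s0=1.0, diffusivity=0.0, aspect_factor=6.0)
        np.testing.assert_allclose(monoexp_signal(p6, [0.0, 2.0, 3.0]), 6.0)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            MonoExpParams(s0=0.0)
        with pytest.raises(ValueError):
            MonoExpParams(diffusivity=-1.0)
        with pytest.raises(ValueError):
            monoexp_signal(MonoExpParams(), -0.1)


class TestBiasedFit:
    def test_noiseless_recovery_is_exact(self):
        b = default_b_values()
        y = monoexp_signal(MonoExpParams(0.9, 1.4, 2.0), b)
        fit = fit_biased_monoexp(y, b, 2.0)
        assert fit.s0 == pytest.approx(0.9, rel=1e-6)
        assert fit.diffusivity == pytest.approx(1.4, rel=1e-6)
        assert fit.sigma == pytest.approx(0.0, abs=1e-6)

    def test_forward_model_recovery_multi_alpha(self):
        """Noiseless data generated by the biased model itself is
        recovered exactly in a joint fit over aspect factors."""
        b1 = default_b_values()
        alphas = np.repeat([1, 2, 3, 4, 5, 6], b1.size)
        b = np.tile(b1, 6)
        y = np.hypot(alphas * np.exp(-2.2 * b), 0.014 * FLOOR)
        fit = fit_biased_monoexp(y, b, alphas)
        assert fit.s0 == pytest.approx(1.0, rel=1e-8)
        assert fit.diffusivity == pytest.approx(2.2, rel=1e-8)
        assert fit.sigma == pytest.approx(0.014, rel=1e-6)

    def test_parameter_recovery_from_simulated_draws(self):
        """The water-simulation design: mean of 1e4 rectified draws per
        b recovers sigma within 10% and D within 2%."""
        b = default_b_values()
        clean = monoexp_signal(MonoExpParams(1.0, 2.2, 1.0), b)
        draws = sample_magnitude(clean, RicianNoiseModel(0.014), 10 ** 4, seed=8)
        fit = fit_biased_monoexp(draws.mean(axis=0), b, 1.0)
        assert fit.sigma == pytest.approx(0.014, rel=0.10)
        assert fit.diffusivity == pytest.approx(2.2, rel=0.02)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_biased_monoexp([1.0, 0.5], [0.0, 1.0], 1.0)
        with pytest.raises(ValueError):
            fit_biased_monoexp([1.0, 0.5, 0.2], [0.5, 1.0, 2.0], 1.0)


class TestThresholdAttenuation:
    def test_published_thresholds_from_measured_snfr(self):
        b1 = threshold_b_value(1.0, 1.0, 1.0 / (60 * FLOOR), 2.2)
        b6 = threshold_b_value(1.0, 6.0, 6.0 / (360 * FLOOR), 2.2)
        assert b1 == pytest.approx(1.3434, abs=1e-3)
        assert b6 == pytest.approx(2.1578, abs=1e-3)
        assert b1 == pytest.approx(1.32, rel=0.02)
        assert b6 == pytest.approx(2.13, rel=0.02)

    def test_zero_crossing_and_domain(self):
        f = 1.05
        snfr_at_zero = 1.0 / np.sqrt(f ** 2 - 1)
        assert threshold_attenuation_from_snfr(snfr_at_zero, f) == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(ValueError):
            threshold_attenuation_from_snfr(60, bias_factor=1.0)
        with pytest.warns(RuntimeWarning):
            beta = threshold_attenuation_from_snfr(1.0, 1.05)
        assert beta < 0

    def test_threshold_grows_with_aspect_factor(self):
        betas = [threshold_attenuation_from_snfr(60 * a) for a in (1, 2, 4, 6)]
        assert all(x < y for x, y in zip(betas, betas[1:]))

    def test_empirical_bias_crossing_matches_formula(self):
        """Simulated decay crosses the 5% bias level within one b-step
        of the closed-form threshold."""
        b = default_b_values()
        clean = monoexp_signal(MonoExpParams(1.0, 2.2, 1.0), b)
        draws = sample_magnitude(clean, RicianNoiseModel(0.014), 2 * 10 ** 4, seed=9)
        ratio = draws.mean(axis=0) / clean
        b_empirical = b[np.argmax(ratio > 1.05)]
        b_formula = threshold_b_value(1.0, 1.0, 0.014, 2.2)
        assert abs(b_empirical - b_formula) <= 0.3 + 1e-9


class TestDotFraction:
    def test_simple_ratio(self):
        assert estimate_fdot(0.2, 1.0) == pytest.approx(0.2)

    def test_upper_bound_overshoot_closed_form(self):
        model = DotModel(f_dot=0.1, d_dot=0.0, d_other=1.0)
        s = dot_signal(model, 1.0, 4.0)
        assert s == pytest.approx(0.1 + 0.9 * np.exp(-4.0), rel=1e-12)
        est = estimate_fdot(s, 1.0)
        assert est - 0.1 == pytest.approx(0.9 * np.exp(-4.0), rel=1e-12)

    def test_vanishing_estimate_without_dot_compartment(self):
        model = DotModel(f_dot=0.0, d_other=1.0)
        ests = [estimate_fdot(dot_signal(model, 1.0, b), 1.0) for b in (2, 6, 12)]
        assert all(x > y for x, y in zip(ests, ests[1:]))
        assert ests[-1] < 1e-5

    def test_masking_and_clipping(self):
        out = estimate_fdot(np.array([0.5, 0.2]), np.array([0.0, 0.1]))
        assert np.isnan(out[0]) and out[1] == pytest.approx(2.0)
        clipped = estimate_fdot(np.array([0.2]), np.array([0.1]), clip=True)
        assert clipped[0] == 1.0

    def test_model_validation(self):
        with pytest.raises(ValueError):
            DotModel(f_dot=1.2)
        with pytest.raises(ValueError):
            DotModel(f_dot=0.1, d_dot=2.0, d_other=1.0)


class TestContrastRatio:
    def test_identical_rois(self, rng):
        img = rng.random((16, 16))
        roi = np.zeros((16, 16), bool)
        roi[4:8, 4:8] = True
        assert contrast_ratio(img, roi, roi) == pytest.approx(1.0)

    def test_two_region_phantom(self, rng):
        img = np.concatenate([np.full(4000, 1.86), np.full(4000, 1.0)])
        img = img + rng.normal(0, 0.02, img.size)
        roi_a = np.arange(8000) < 4000
        assert contrast_ratio(img, roi_a, ~roi_a) == pytest.approx(1.86, rel=0.01)

    def test_noise_floor_compresses_contrast(self):
        """Adding a rectified-noise floor to both regions pulls the
        ratio toward 1 -- the accuracy argument for thick slices."""
        floor = rician_expected_signal(0.0, 0.3)
        a = rician_expected_signal(1.86, 0.3)
        b = rician_expected_signal(1.0, 0.3)
        assert a / b < 1.86
        assert a / b > 1.0
        assert floor > 0

    def test_empty_roi_error(self):
        with pytest.raises(ValueError):
            contrast_ratio(np.ones((4, 4)), np.zeros((4, 4), bool), np.ones((4, 4), bool))
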