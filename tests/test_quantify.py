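import numpy as np
import pytest

from tearmrm.quantify import (
    estimate_conversion_factor,
    fit_calibration,
    integrate_peak,
    quantify,
    response_ratio,
    strip_volume,
)
from tearmrm.synthetic import StripModel, simulate_strip_wetting

SEVEN_LEVELS = (0.1, 0.5, 1.0, 5.0, 10.0, 50.0, 100.0)


def gaussian_trace(area, rt, sigma, n=2000, span=17.0):
    t = np.linspace(0.0, span, n)
    y = area / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((t - rt) / sigma) ** 2)
    return t, y


class TestIntegratePeak:
    def test_gaussian_area_recovered(self):
        t, y = gaussian_trace(1234.0, 9.85, 0.1)
        area = integrate_peak(t, y, (9.85 - 0.6, 9.85 + 0.6))
        assert area == pytest.approx(1234.0, rel=0.01)

    def test_flat_zero_trace(self):
        t = np.linspace(0, 17, 500)
        assert integrate_peak(t, np.zeros_like(t), (5.0, 6.0)) == 0.0

    def test_disjoint_window_additivity(self):
        t, y1 = gaussian_trace(500.0, 5.0, 0.1)
        _, y2 = gaussian_trace(800.0, 12.0, 0.1)
        y = y1 + y2
        a1 = integrate_peak(t, y, (4.0, 6.0))
        a2 = integrate_peak(t, y, (11.0, 13.0))
        assert a1 + a2 == pytest.approx(1300.0, rel=0.01)

    def test_baseline_subtraction(self):
        t, y = gaussian_trace(1000.0, 9.0, 0.1)
        area = integrate_peak(t, y + 50.0, (8.4, 9.6))
        assert area == pytest.approx(1000.0, rel=0.01)

    def test_integrates_simulated_chromatogram(self, rng):
        from tearmrm.synthetic import InstrumentModel, simulate_chromatogram

        t, y = simulate_chromatogram(5000.0, 9.85, InstrumentModel(), rng)
        area = integrate_peak(t, y, (9.25, 10.45))
        assert area == pytest.approx(5000.0, rel=0.05)

    def test_empty_window_rejected(self):
        t = np.linspace(0, 17, 100)
        with pytest.raises(ValueError):
            integrate_peak(t, np.zeros_like(t), (20.0, 21.0))
        with pytest.raises(ValueError):
            integrate_peak(t, np.zeros_like(t), (6.0, 5.0))


class TestResponseRatio:
    def test_unity(self):
        assert response_ratio(100.0, 100.0) == 1.0

    def test_zero_analyte(self):
        assert response_ratio(0.0, 100.0) == 0.0

    def test_shared_loss_invariance(self, rng):
        for _ in range(50):
            a, i = rng.uniform(10, 1000, size=2)
            lam = rng.uniform(0.5, 1.0)
            assert response_ratio(lam * a, lam * i) == pytest.approx(
                response_ratio(a, i), rel=1e-12
            )

    def test_zero_is_area_rejected(self):
        with pytest.raises(ValueError, match="unusable"):
            response_ratio(10.0, 0.0)


class TestFitCalibration:
    def test_exact_linear_input(self):
        levels = [(c, 0.02 * c) for c in SEVEN_LEVELS]
        curve = fit_calibration(levels, weighting="1/x2")
        assert curve.slope == pytest.approx(0.02, abs=1e-9)
        assert curve.intercept == pytest.approx(0.0, abs=1e-9)
        assert all(a == pytest.approx(100.0, abs=1e-6) for a in curve.accuracy_percent)

    @pytest.mark.parametrize("weighting", ["none", "1/x", "1/x2"])
    def test_exact_input_all_weightings(self, weighting):
        levels = [(c, 0.05 * c + 0.001) for c in SEVEN_LEVELS]
        curve = fit_calibration(levels, weighting=weighting)
        assert curve.slope == pytest.approx(0.05, abs=1e-9)
        assert curve.intercept == pytest.approx(0.001, abs=1e-9)

    def test_weighting_improves_low_end_accuracy(self):
        # Heteroscedastic ratios (constant CV): unweighted fits let the top
        # levels pull the intercept, degrading low-end back-calculation.
        rng = np.random.default_rng(42)
        err_none, err_w = [], []
        for _ in range(100):
            ratios = [0.02 * c * rng.lognormal(0, 0.05) for c in SEVEN_LEVELS]
            levels = list(zip(SEVEN_LEVELS, ratios))
            for weighting, errs in (("none", err_none), ("1/x2", err_w)):
                curve = fit_calibration(levels, weighting=weighting)
                errs.append(abs(curve.accuracy_percent[0] - 100.0))
        assert np.mean(err_w) < np.mean(err_none)

    def test_top_level_outlier_barely_moves_low_end_with_1_over_x2(self):
        # With 1/x2 every level carries equal relative influence, so a 5%
        # outlier at the top shifts low-end accuracy by < 1%; unweighted,
        # the top level dominates the slope and the shift is several-fold.
        clean = [(c, 0.02 * c) for c in SEVEN_LEVELS]
        spiked = clean[:-1] + [(100.0, 0.02 * 100.0 * 1.05)]
        c_clean = fit_calibration(clean, weighting="1/x2")
        c_spiked = fit_calibration(spiked, weighting="1/x2")
        for a, b in zip(c_clean.accuracy_percent[:3], c_spiked.accuracy_percent[:3]):
            assert abs(a - b) < 1.0
        u_clean = fit_calibration(clean, weighting="none")
        u_spiked = fit_calibration(spiked, weighting="none")
        weighted_shift = abs(c_spiked.accuracy_percent[0] - c_clean.accuracy_percent[0])
        unweighted_shift = abs(u_spiked.accuracy_percent[0] - u_clean.accuracy_percent[0])
        assert unweighted_shift > 3 * weighted_shift

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError, match="5"):
            fit_calibration([(1, 0.1), (2, 0.2), (3, 0.3), (4, 0.4)])

    def test_duplicate_concentrations_rejected(self):
        levels = [(1, 0.1), (2, 0.2), (2, 0.21), (5, 0.5), (10, 1.0)]
        with pytest.raises(ValueError, match="strictly increasing"):
            fit_calibration(levels)

    def test_negative_slope_rejected(self):
        levels = [(c, -0.02 * c + 3) for c in SEVEN_LEVELS]
        with pytest.raises(ValueError, match="slope"):
            fit_calibration(levels)


class TestQuantify:
    @pytest.fixture
    def curve(self):
        return fit_calibration([(c, 0.02 * c) for c in SEVEN_LEVELS])

    def test_inverse_identity_on_curve_point(self, curve):
        ratio = curve.slope * 10.0 + curve.intercept
        assert quantify(ratio, curve).concentration_ug_per_ml == pytest.approx(
            10.0, rel=1e-9
        )

    def test_zero_ratio_zero_intercept(self, curve):
        assert quantify(0.0, curve).concentration_ug_per_ml == 0.0

    def test_negative_estimate_clamped_and_flagged(self):
        curve = fit_calibration([(c, 0.02 * c + 0.5) for c in SEVEN_LEVELS])
        result = quantify(0.0, curve)
        assert result.concentration_ug_per_ml == 0.0
        assert result.clamped

    def test_above_top_level_flagged_extrapolated(self, curve):
        result = quantify(curve.slope * 150.0, curve)
        assert result.extrapolated

    def test_negative_ratio_rejected(self, curve):
        with pytest.raises(ValueError):
            quantify(-0.1, curve)


class TestConversionFactor:
    VOLUMES = (5, 10, 15, 20, 25, 30, 35, 40)

    def test_exact_data(self):
        v = np.repeat(self.VOLUMES, 3).astype(float)
        factor = estimate_conversion_factor(v, 1.15 * v)
        assert factor.estimate_mm_per_ul == pytest.approx(1.15, abs=1e-12)
        assert factor.sd_mm_per_ul == pytest.approx(0.0, abs=1e-12)

    def test_parameter_recovery_with_noise(self):
        rng = np.random.default_rng(4)
        model = StripModel(conversion_factor_mm_per_ul=1.15, length_noise_sd_mm=0.3)
        v, l = [], []
        for volume in self.VOLUMES:
            for _ in range(3):
                v.append(volume)
                l.append(simulate_strip_wetting(volume, model, rng))
        factor = estimate_conversion_factor(v, l)
        assert factor.estimate_mm_per_ul == pytest.approx(1.15, rel=0.02)

    def test_scale_equivariance(self):
        v = np.repeat(self.VOLUMES, 3).astype(float)
        l = 1.15 * v + 0.1
        f1 = estimate_conversion_factor(v, l)
        f2 = estimate_conversion_factor(v, 2 * l)
        assert f2.estimate_mm_per_ul == pytest.approx(2 * f1.estimate_mm_per_ul)

    def test_unbiased_over_many_seeds(self):
        # 500 seeded repetitions: mean estimate within 3 SE of truth.
        model = StripModel(conversion_factor_mm_per_ul=1.15, length_noise_sd_mm=0.3)
        rng = np.random.default_rng(99)
        v = np.repeat(self.VOLUMES, 3).astype(float)
        estimates = []
        for _ in range(500):
            lengths = [simulate_strip_wetting(x, model, rng) for x in v]
            estimates.append(estimate_conversion_factor(v, lengths).estimate_mm_per_ul)
        estimates = np.array(estimates)
        se = estimates.std(ddof=1) / np.sqrt(len(estimates))
        assert abs(estimates.mean() - 1.15) < 3 * se

    def test_fewer_than_three_distinct_volumes_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            estimate_conversion_factor([5, 5, 10, 10], [5.75, 5.7, 11.5, 11.4])


class TestStripVolume:
    def test_reference_arithmetic(self):
        v = np.repeat((5, 10, 15), 2).astype(float)
        factor = estimate_conversion_factor(v, 1.15 * v)
        assert strip_volume(11.5, factor) == pytest.approx(10.0)

    def test_zero_length(self):
        assert strip_volume(0.0, 1.15) == 0.0

    def test_round_trip_with_noiseless_wetting(self):
        model = StripModel(length_noise_sd_mm=0.0)
        for v in (1.0, 7.3, 25.0):
            length = simulate_strip_wetting(v, model, rng=0)
            assert strip_volume(length, model.conversion_factor_mm_per_ul) == pytest.approx(v)

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            strip_volume(-1.0, 1.15)
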