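"""Derivative filters: weights, exactness, point-loss contracts, SNR."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spectrocal as sc
from spectrocal.filters import NONE_FILTER, sbsf_coefficients

from oracles import onesided_deriv_bruteforce, sg_weights_bruteforce


def spectrum_from(values, start=0.0, step=1.0, sid="A"):
    n = len(values)
    return sc.Spectrum(start + step * np.arange(n), np.asarray(values, float), sid, 1)


class TestGSCoefficients:
    @pytest.mark.parametrize(
        "m,degree,deriv",
        [(2, 2, 0), (2, 2, 1), (5, 2, 1), (5, 3, 1), (7, 4, 2), (10, 2, 1)],
    )
    def test_matches_bruteforce_least_squares(self, m, degree, deriv):
        got = sc.gs_coefficients(m, degree, deriv)
        expected = sg_weights_bruteforce(m, degree, deriv)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_five_point_quadratic_smoother(self):
        np.testing.assert_allclose(
            sc.gs_coefficients(2, 2, 0), np.array([-3, 12, 17, 12, -3]) / 35.0
        )

    @pytest.mark.parametrize("m,degree", [(2, 2), (5, 2), (10, 4)])
    def test_smoothing_weights_sum_to_one(self, m, degree):
        assert sc.gs_coefficients(m, degree, 0).sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("m,degree", [(2, 2), (5, 2), (10, 3)])
    def test_derivative_weights_antisymmetric_and_annihilate_constants(self, m, degree):
        w = sc.gs_coefficients(m, degree, 1)
        np.testing.assert_allclose(w, -w[::-1], atol=1e-12)
        assert abs(w.sum()) < 1e-12

    def test_window_too_small_for_degree(self):
        with pytest.raises(ValueError, match="window too small"):
            sc.gs_coefficients(1, 4, 1)


class TestGSFirstDerivative:
    def test_linear_spectrum_gives_constant_slope(self):
        s = spectrum_from(3.5 * np.arange(50.0) + 2.0)
        out = sc.gs_first_derivative(s, sc.FilterSpec("GS", window=5, degree=2))
        np.testing.assert_allclose(out.values, 3.5, rtol=1e-10)

    @pytest.mark.parametrize("m", [2, 5, 10])
    def test_symmetric_point_loss(self, m):
        n = 100
        s = spectrum_from(np.random.default_rng(0).normal(size=n))
        out = sc.gs_first_derivative(s, sc.FilterSpec("GS", window=m, degree=2))
        assert len(out) == n - 2 * m
        assert out.wavelengths_nm[0] == s.wavelengths_nm[m]
        assert out.wavelengths_nm[-1] == s.wavelengths_nm[-m - 1]

    def test_grid_step_scaling(self):
        # derivative is per nm, independent of the grid step
        v = (np.arange(40.0) * 0.5) ** 2
        fine = spectrum_from(v, step=0.5)
        out = sc.gs_first_derivative(fine, sc.FilterSpec("GS", window=3, degree=2))
        np.testing.assert_allclose(out.values, 2 * out.wavelengths_nm, rtol=1e-9)

    def test_sine_matches_analytic_derivative(self):
        # frozen oracle bound: 11-point quadratic filter on a 400-nm-period
        # sine leaves < 1e-3 relative error vs the analytic cosine
        w = np.arange(0.0, 2000.0)
        period = 400.0
        s = sc.Spectrum(w, np.sin(2 * np.pi * w / period), "A", 1)
        out = sc.gs_first_derivative(s, sc.FilterSpec("GS", window=5, degree=2))
        amp = 2 * np.pi / period
        analytic = amp * np.cos(2 * np.pi * out.wavelengths_nm / period)
        assert np.max(np.abs(out.values - analytic)) < 1e-3 * amp

    def test_too_short_spectrum_rejected(self):
        s = spectrum_from(np.arange(5.0))
        with pytest.raises(ValueError, match="shorter"):
            sc.gs_first_derivative(s, sc.FilterSpec("GS", window=10, degree=2))

    def test_multi_segment_equals_per_segment(self):
        rng = np.random.default_rng(3)
        w = np.arange(250.0, 2001.0)
        s = sc.Spectrum(w, rng.normal(size=w.size), "A", 1)
        trimmed = sc.trim_regions(s, sc.ZERO_ORDER_REGIONS)
        spec = sc.GS_DEFAULT
        joint = sc.gs_first_derivative(trimmed, spec)
        seg1 = sc.gs_first_derivative(sc.trim_regions(s, sc.RegionSet(((270, 850),))), spec)
        seg2 = sc.gs_first_derivative(sc.trim_regions(s, sc.RegionSet(((907, 2000),))), spec)
        np.testing.assert_array_equal(
            joint.values, np.concatenate([seg1.values, seg2.values])
        )


class TestSBSFFirstDerivative:
    def test_linear_spectrum_gives_constant_slope(self):
        s = spectrum_from(-1.25 * np.arange(30.0) + 7.0)
        out = sc.sbsf_first_derivative(s, sc.SBSF_DEFAULT)
        np.testing.assert_allclose(out.values, -1.25, rtol=1e-10)

    def test_exact_on_cubics(self):
        w = np.arange(100.0)
        poly = np.polynomial.Polynomial([2.0, -0.3, 0.01, -2e-4])
        s = spectrum_from(poly(w))
        out = sc.sbsf_first_derivative(s, sc.SBSF_DEFAULT)
        analytic = poly.deriv()(out.wavelengths_nm)
        scale = np.max(np.abs(analytic))
        np.testing.assert_allclose(out.values, analytic, rtol=0, atol=1e-8 * scale)

    @pytest.mark.parametrize("window,degree", [(2, 3), (1, 1), (5, 3), (3, 2)])
    def test_red_end_only_point_loss(self, window, degree):
        n = 60
        s = spectrum_from(np.random.default_rng(1).normal(size=n))
        out = sc.sbsf_first_derivative(s, sc.FilterSpec("SBSF", window=window, degree=degree))
        assert out.wavelengths_nm[0] == s.wavelengths_nm[0]
        assert len(out) == n - (window + degree)
        assert out.wavelengths_nm[-1] < s.wavelengths_nm[-1]

    def test_matches_bruteforce_forward_fit(self):
        rng = np.random.default_rng(8)
        v = rng.normal(size=80)
        s = spectrum_from(v, step=2.0)
        out = sc.sbsf_first_derivative(s, sc.SBSF_DEFAULT)
        expected = onesided_deriv_bruteforce(v, footprint=5, degree=3, step=2.0)
        np.testing.assert_allclose(out.values, expected, atol=1e-10)

    def test_too_short_spectrum_rejected(self):
        s = spectrum_from(np.arange(4.0))
        with pytest.raises(ValueError, match="shorter"):
            sc.sbsf_first_derivative(s, sc.FilterSpec("SBSF", window=2, degree=3))


class TestFilterProperties:
    @pytest.mark.parametrize(
        "spec",
        [sc.FilterSpec("GS", 4, 2), sc.FilterSpec("GS", 10, 2), sc.SBSF_DEFAULT],
        ids=["gs4", "gs10", "sbsf"],
    )
    def test_polynomial_exactness_at_configured_degree(self, spec):
        w = np.arange(120.0)
        coeffs = [1.0, -0.5, 3e-3, -1e-5][: spec.degree + 1]
        poly = np.polynomial.Polynomial(coeffs)
        out = sc.apply_filter(spectrum_from(poly(w)), spec)
        analytic = poly.deriv()(out.wavelengths_nm)
        np.testing.assert_allclose(out.values, analytic, atol=1e-8 * max(1, np.abs(analytic).max()))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        a=st.floats(-5, 5, allow_nan=False),
        b=st.floats(-5, 5, allow_nan=False),
        seed=st.integers(0, 100),
    )
    def test_linearity(self, a, b, seed):
        rng = np.random.default_rng(seed)
        v1, v2 = rng.normal(size=(2, 60))
        spec = sc.FilterSpec("GS", 4, 2)
        combined = sc.apply_filter(spectrum_from(a * v1 + b * v2), spec).values
        parts = (
            a * sc.apply_filter(spectrum_from(v1), spec).values
            + b * sc.apply_filter(spectrum_from(v2), spec).values
        )
        np.testing.assert_allclose(combined, parts, atol=1e-9 * (1 + abs(a) + abs(b)))

    def test_gs_attenuates_narrow_peaks_more_with_larger_window(self):
        # a Gaussian band narrower than the window: the derivative extremum
        # shrinks as the window grows (the smoothing/information trade-off)
        w = np.arange(0.0, 400.0)
        band = np.exp(-((w - 200.0) ** 2) / (2 * 4.0**2))
        extrema = []
        for m in (3, 8, 15):
            out = sc.gs_first_derivative(
                sc.Spectrum(w, band, "A", 1), sc.FilterSpec("GS", m, 2)
            )
            extrema.append(np.abs(out.values).max())
        assert extrema[0] > extrema[1] > extrema[2]

    def test_none_filter_passthrough(self):
        s = spectrum_from(np.arange(10.0))
        assert sc.apply_filter(s, NONE_FILTER) is s


class TestSNRGain:
    @staticmethod
    def smooth_truth(n=1200):
        w = np.arange(float(n))
        v = 10 + 5 * np.sin(2 * np.pi * w / 500.0) + 3 * np.exp(-((w - 700) ** 2) / (2 * 80**2))
        return sc.Spectrum(w, v, "A", 1)

    def test_zero_noise_ratio_near_one(self):
        w = np.arange(200.0)
        truth = sc.Spectrum(w, 0.5 * w + 3.0, "A", 1)
        # both estimators are exact up to rounding; the guarded ratio of two
        # near-zero RMS errors sits at 1 within numerical tolerance
        ratio = sc.snr_gain(truth, truth, sc.FilterSpec("GS", 5, 2))
        assert ratio == pytest.approx(1.0, abs=1e-2)

    def test_filter_beats_naive_differencing_under_noise(self):
        truth = self.smooth_truth()
        rng = np.random.default_rng(17)
        gains = []
        for _ in range(100):
            noisy = sc.Spectrum(
                truth.wavelengths_nm, truth.values + rng.normal(0, 0.05, len(truth)), "A", 1
            )
            gains.append(sc.snr_gain(noisy, truth, sc.FilterSpec("GS", 5, 2)))
        assert np.mean(gains) > 1.0

    def test_gain_increases_with_window(self):
        truth = self.smooth_truth()
        rng = np.random.default_rng(23)
        mean_gain = {}
        noises = [rng.normal(0, 0.05, len(truth)) for _ in range(100)]
        for m in (2, 5, 7):
            gains = [
                sc.snr_gain(
                    sc.Spectrum(truth.wavelengths_nm, truth.values + nz, "A", 1),
                    truth,
                    sc.FilterSpec("GS", m, 2),
                )
                for nz in noises
            ]
            mean_gain[m] = np.mean(gains)
        assert mean_gain[2] < mean_gain[5] < mean_gain[7]

    def test_grid_mismatch_rejected(self):
        a = spectrum_from(np.arange(10.0))
        b = spectrum_from(np.arange(10.0), start=1.0)
        with pytest.raises(ValueError, match="share one grid"):
            sc.snr_gain(a, b, sc.FilterSpec("GS", 2, 2))
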