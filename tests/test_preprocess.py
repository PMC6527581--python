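"""Co-addition, despiking, masked polynomial baseline fit, normalization."""

import numpy as np
import pytest

from ramanprobe import (
    AnalysisWindows,
    ExposureStack,
    GroundTruth,
    ProbeModel,
    Spectrum,
    coadd,
    despike,
    fit_baseline,
    normalize_peak,
    preprocess_stack,
    simulate_spectrum,
    subtract_baseline,
)
from ramanprobe.peaks import peak_fwhm, peak_mean
from ramanprobe.preprocess import BaselineFit
from ramanprobe.simulate import make_axis, pseudo_voigt
from ramanprobe.spectra import AxisMismatchError


def _poly_on_window(axis, coeffs, lo=2000.0, hi=2300.0):
    x = 2.0 * (axis - lo) / (hi - lo) - 1.0
    return np.polynomial.polynomial.polyval(x, coeffs)


class TestCoadd:
    def test_single_exposure_mean_is_identity(self, axis):
        stack = ExposureStack(shift=axis, exposures=np.sin(axis)[None, :] + 2)
        spec = coadd(stack, "mean")
        np.testing.assert_array_equal(spec.intensity, stack.exposures[0])
        assert spec.meta["n_exposures"] == 1

    def test_mean_of_ones_and_threes_is_twos(self, axis):
        stack = ExposureStack(
            shift=axis, exposures=np.vstack([np.ones_like(axis), 3 * np.ones_like(axis)])
        )
        assert np.all(coadd(stack, "mean").intensity == 2.0)
        assert np.all(coadd(stack, "sum").intensity == 4.0)

    def test_mean_matches_naive_loop_oracle(self, axis):
        rng = np.random.default_rng(12)
        exposures = rng.poisson(200, size=(50, axis.size)).astype(float)
        stack = ExposureStack(shift=axis, exposures=exposures)
        oracle = np.zeros(axis.size)
        for row in exposures:
            oracle += row
        oracle /= 50
        np.testing.assert_allclose(coadd(stack).intensity, oracle, rtol=1e-12)

    def test_empty_stack_rejected(self, axis):
        with pytest.raises(ValueError):
            ExposureStack(shift=axis, exposures=np.empty((0, axis.size)))
        with pytest.raises(ValueError):
            coadd(ExposureStack(shift=axis, exposures=np.ones((1, axis.size))), mode="median")


class TestDespike:
    def test_clean_stack_unchanged(self, axis):
        rng = np.random.default_rng(3)
        stack = ExposureStack(shift=axis, exposures=rng.normal(100, 5, size=(20, axis.size)))
        out = despike(stack, z_thresh=8.0)
        np.testing.assert_array_equal(out.exposures, stack.exposures)
        assert out.meta["despiked_points"] == 0

    def test_single_injected_spike_replaced(self, axis):
        rng = np.random.default_rng(4)
        exposures = rng.normal(100, 2, size=(10, axis.size))
        exposures[4, 100] += 50 * 2  # 50-sigma single-point spike
        stack = ExposureStack(shift=axis, exposures=exposures)
        out = despike(stack, z_thresh=8.0)
        changed = np.argwhere(out.exposures != exposures)
        assert changed.tolist() == [[4, 100]]
        med = np.median(exposures[:, 100])
        assert out.exposures[4, 100] == med

    def test_two_exposures_pass_through_with_warning(self, axis, caplog):
        stack = ExposureStack(shift=axis, exposures=np.ones((2, axis.size)))
        with caplog.at_level("WARNING"):
            out = despike(stack)
        assert out is stack
        assert "despike" in caplog.text


class TestBaselineFit:
    def test_pure_polynomial_reproduced(self, axis, windows):
        coeffs = [50.0, -3.0, 7.0, 0.5, -2.0, 1.0, 0.3, -0.2]  # degree 7
        spec = Spectrum(shift=axis, intensity=_poly_on_window(axis, coeffs))
        fit = fit_baseline(spec, windows)
        scale = np.abs(spec.intensity).max()
        assert fit.residual_rms < 1e-8 * scale
        mask = windows.in_baseline(axis)
        np.testing.assert_allclose(
            fit.evaluate(axis[mask]), spec.intensity[mask], atol=1e-8 * scale
        )

    def test_masked_band_does_not_bias_fit(self, axis, windows):
        """Baseline recovered to 1e-6 relative when the band is confined to the mask."""
        coeffs = [300.0, -20.0, 10.0, 4.0]
        truth = _poly_on_window(axis, coeffs)
        band = 2000.0 * pseudo_voigt(axis, 2115.0, 5.0, 0.0)  # Gaussian, inside the hole
        spec = Spectrum(shift=axis, intensity=truth + band)
        fit = fit_baseline(spec, windows)
        unmasked = windows.in_baseline(axis) & ~windows.in_peak(axis)
        rel = np.abs(fit.evaluate(axis[unmasked]) - truth[unmasked]) / np.abs(truth[unmasked])
        assert rel.max() < 1e-6

    def test_flat_spectrum_gives_constant(self, axis, windows):
        spec = Spectrum(shift=axis, intensity=np.full(axis.size, 5.0))
        fit = fit_baseline(spec, windows)
        assert abs(fit.coeffs[0] - 5.0) < 1e-9
        assert np.abs(fit.coeffs[1:]).max() < 1e-9

    def test_insufficient_points_error(self, windows):
        axis = np.linspace(2000, 2300, 10)  # only a handful outside the mask
        spec = Spectrum(shift=axis, intensity=np.ones(10))
        with pytest.raises(ValueError, match="unmasked"):
            fit_baseline(spec, windows, degree=9)

    def test_spectrum_must_cover_window(self, windows):
        axis = np.linspace(2050, 2200, 100)
        with pytest.raises(ValueError, match="cover"):
            fit_baseline(Spectrum(shift=axis, intensity=np.ones(100)), windows)

    def test_residuals_orthogonal_to_basis(self, axis, windows):
        """The least-squares fit is a true projection."""
        rng = np.random.default_rng(8)
        spec = Spectrum(shift=axis, intensity=rng.normal(100, 10, axis.size))
        fit = fit_baseline(spec, windows)
        unmasked = windows.in_baseline(axis) & ~windows.in_peak(axis)
        x = 2.0 * (axis[unmasked] - 2000.0) / 300.0 - 1.0
        resid = spec.intensity[unmasked] - fit.evaluate(axis[unmasked])
        vand = np.polynomial.polynomial.polyvander(x, fit.degree)
        for k in range(fit.degree + 1):
            v = vand[:, k]
            cosine = abs(v @ resid) / (np.linalg.norm(v) * np.linalg.norm(resid))
            assert cosine < 1e-6

    def test_invariant_to_adding_low_degree_polynomial(self, axis, windows):
        rng = np.random.default_rng(9)
        base = rng.normal(100, 5, axis.size) + 500 * pseudo_voigt(axis, 2115, 6, 0.0)
        added = _poly_on_window(axis, [40.0, -12.0, 3.0, 1.0, -0.5, 0.2, 0.1, -0.05])
        a = subtract_baseline(Spectrum(shift=axis, intensity=base), fit_baseline(Spectrum(shift=axis, intensity=base), windows))
        b = subtract_baseline(
            Spectrum(shift=axis, intensity=base + added),
            fit_baseline(Spectrum(shift=axis, intensity=base + added), windows),
        )
        scale = np.abs(a.intensity).max()
        np.testing.assert_allclose(b.intensity, a.intensity, atol=1e-6 * scale)


class TestSubtract:
    def test_self_subtraction_of_pure_polynomial_is_zero(self, axis, windows):
        spec = Spectrum(shift=axis, intensity=_poly_on_window(axis, [10.0, 2.0, -1.0]))
        out = subtract_baseline(spec, fit_baseline(spec, windows))
        assert np.abs(out.intensity).max() < 1e-8 * np.abs(spec.intensity).max()

    def test_band_recovery(self, axis, windows):
        truth = _poly_on_window(axis, [250.0, -30.0, 12.0, 5.0])
        band = 1500.0 * pseudo_voigt(axis, 2116.0, 5.0, 0.0)
        spec = Spectrum(shift=axis, intensity=truth + band)
        out = subtract_baseline(spec, fit_baseline(spec, windows))
        mask = windows.in_baseline(axis)
        assert np.abs(out.intensity - band[mask]).max() < 1e-4 * 1500.0

    def test_zero_fit_is_identity_and_idempotent(self, axis, windows):
        spec = Spectrum(shift=axis, intensity=np.cos(axis / 50.0) + 2)
        mask = windows.in_baseline(axis)
        zero = BaselineFit(
            degree=7,
            coeffs=np.zeros(8),
            windows=windows,
            domain=windows.baseline,
            residual_rms=0.0,
            n_fit_points=int(mask.sum()),
            fit_axis=axis[mask],
        )
        once = subtract_baseline(spec, zero)
        twice = subtract_baseline(once, zero)
        np.testing.assert_array_equal(once.intensity, spec.intensity[mask])
        np.testing.assert_array_equal(twice.intensity, once.intensity)

    def test_axis_mismatch_error(self, axis, windows):
        spec = Spectrum(shift=axis, intensity=np.ones(axis.size))
        fit = fit_baseline(spec, windows)
        other = Spectrum(shift=axis + 0.5, intensity=np.ones(axis.size))
        with pytest.raises(AxisMismatchError):
            subtract_baseline(other, fit)


class TestNormalize:
    def test_peak_max_becomes_exactly_one(self, axis, windows):
        spec = Spectrum(shift=axis, intensity=2.0 * pseudo_voigt(axis, 2118, 10, 0.5))
        out = normalize_peak(spec, windows)
        assert out.intensity[windows.in_peak(axis)].max() == 1.0
        assert out.normalized

    def test_idempotent(self, axis, windows):
        spec = Spectrum(shift=axis, intensity=3.7 * pseudo_voigt(axis, 2118, 10, 0.5))
        once = normalize_peak(spec, windows)
        twice = normalize_peak(once, windows)
        np.testing.assert_allclose(twice.intensity, once.intensity, rtol=1e-12)

    def test_preserves_centroid_and_fwhm(self, axis, windows):
        spec = Spectrum(shift=axis, intensity=40.0 * pseudo_voigt(axis, 2117, 9, 0.3))
        out = normalize_peak(spec, windows)
        assert abs(peak_mean(out, windows) - peak_mean(spec, windows)) < 1e-9
        assert abs(peak_fwhm(out, windows) - peak_fwhm(spec, windows)) < 1e-9

    def test_no_band_error(self, axis, windows):
        with pytest.raises(ValueError, match="no detectable band"):
            normalize_peak(Spectrum(shift=axis, intensity=np.full(axis.size, -1.0)), windows)


def test_full_chain_deterministic():
    model = ProbeModel()
    truth = GroundTruth(fraction_sequestered=0.5, seed=77)
    stack, _ = simulate_spectrum(model, truth)
    a, fit_a = preprocess_stack(stack)
    b, fit_b = preprocess_stack(stack)
    assert np.array_equal(a.intensity, b.intensity)
    assert np.array_equal(fit_a.coeffs, fit_b.coeffs)


def test_coadded_chain_approaches_noise_free_chain():
    """Mean co-addition then preprocessing stays within O(noise/sqrt(n)) of the
    noise-free chain."""
    model = ProbeModel()
    noisy, _ = simulate_spectrum(model, GroundTruth(fraction_sequestered=0.5, seed=21), n_exposures=60)
    clean, _ = simulate_spectrum(model, GroundTruth(fraction_sequestered=0.5, noise_scale=0.0, seed=21), n_exposures=1)
    spec_noisy, _ = preprocess_stack(noisy)
    spec_clean, _ = preprocess_stack(clean)
    # per-point co-added sigma ~ sqrt(1200)/sqrt(60) ~ 4.5 counts on a 1000-count band
    assert np.abs(spec_noisy.intensity - spec_clean.intensity).max() < 0.05


def test_windows_validation():
    with pytest.raises(ValueError):
        AnalysisWindows(baseline=(2000, 2300), peak=(1990, 2130))
    with pytest.raises(ValueError):
        AnalysisWindows(baseline=(2300, 2000), peak=(2100, 2130))
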