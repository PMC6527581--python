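"""Per-spectrum band statistics: mode, windowed centroid mean, FWHM.

These are the nonparametric summaries reported per spectrum. "Inspection" is
operationalized deterministically: the mode is the grid argmax in the peak
window (ties broken toward lower wavenumber), and the FWHM comes from linearly
interpolated half-maximum crossings nearest the mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .preprocess import DEFAULT_WINDOWS, AnalysisWindows
from .spectra import Spectrum

logger = logging.getLogger(__name__)

__all__ = ["PeakStats", "peak_mode", "peak_mean", "peak_fwhm", "summarize", "PeakStatsExtractor"]


@dataclass
class PeakStats:
    """Summary statistics of the probe band, all in cm^-1."""

    mode: float
    mean: float
    fwhm: float
    windows: AnalysisWindows
    probe: str = ""


def _require_window_coverage(spec: Spectrum, windows: AnalysisWindows) -> np.ndarray:
    plo, phi = windows.peak
    if spec.shift[0] > plo or spec.shift[-1] < phi:
        raise ValueError(
            f"spectrum [{spec.shift[0]}, {spec.shift[-1]}] does not cover the "
            f"peak window [{plo}, {phi}]"
        )
    mask = windows.in_peak(spec.shift)
    if not mask.any():
        raise ValueError("no sampled points inside the peak window")
    return mask


def peak_mode(spec: Spectrum, windows: AnalysisWindows = DEFAULT_WINDOWS) -> float:
    """Axis location of the maximum intensity inside the peak window.

    Exact ties are broken toward lower wavenumber (argmax on an ascending
    axis returns the first maximum).
    """
    mask = _require_window_coverage(spec, windows)
    sub = spec.intensity[mask]
    idx = int(np.argmax(sub))
    if np.sum(sub == sub[idx]) > 1:
        logger.info("peak_mode: tie broken toward lower wavenumber")
    return float(spec.shift[mask][idx])


def peak_mean(spec: Spectrum, windows: AnalysisWindows = DEFAULT_WINDOWS) -> float:
    """Intensity-weighted centroid over the peak window.

    Negative intensities (possible after baseline subtraction) are clipped to
    zero inside the weights only; the spectrum itself is untouched. The
    centroid is invariant under uniform intensity scaling, so it is the same
    before and after peak normalization.
    """
    mask = _require_window_coverage(spec, windows)
    weights = np.clip(spec.intensity[mask], 0.0, None)
    total = weights.sum()
    if total <= 0:
        raise ValueError("no positive intensity in the peak window")
    return float(np.sum(spec.shift[mask] * weights) / total)


def peak_fwhm(spec: Spectrum, windows: AnalysisWindows = DEFAULT_WINDOWS) -> float:
    """Full width at half maximum by interpolated crossings nearest the mode.

    From the mode, walk outward left and right to the first crossings of half
    the peak maximum and linearly interpolate each crossing position. The
    crossings may fall outside the peak window but must lie inside the
    baseline window; a band still above half maximum at the baseline-window
    edge is truncated and raises.
    """
    _require_window_coverage(spec, windows)
    base_mask = windows.in_baseline(spec.shift)
    shift = spec.shift[base_mask]
    intensity = spec.intensity[base_mask]
    peak_in_window = windows.in_peak(shift)
    i_mode = int(np.flatnonzero(peak_in_window)[np.argmax(intensity[peak_in_window])])
    peak_val = intensity[i_mode]
    if peak_val <= 0:
        raise ValueError("non-positive peak maximum")
    half = 0.5 * peak_val

    def cross(direction: int) -> float:
        j = i_mode
        while 0 <= j + direction < shift.size:
            k = j + direction
            if intensity[k] < half:
                # linear interpolation between j (>= half) and k (< half)
                frac = (half - intensity[j]) / (intensity[k] - intensity[j])
                return float(shift[j] + frac * (shift[k] - shift[j]))
            j = k
        raise ValueError(
            "band truncated: no half-maximum crossing inside the baseline window "
            f"({'right' if direction > 0 else 'left'} side)"
        )

    left = cross(-1)
    right = cross(+1)
    return right - left


def summarize(spec: Spectrum, windows: AnalysisWindows = DEFAULT_WINDOWS) -> PeakStats:
    """Bundle mode, windowed mean, and FWHM for one spectrum."""
    stats = PeakStats(
        mode=peak_mode(spec, windows),
        mean=peak_mean(spec, windows),
        fwhm=peak_fwhm(spec, windows),
        windows=windows,
        probe=spec.probe,
    )
    logger.info(
        "%s: mode=%.2f mean=%.2f fwhm=%.2f",
        spec.sample_id or "spectrum",
        stats.mode,
        stats.mean,
        stats.fwhm,
    )
    return stats


class PeakStatsExtractor(BaseEstimator, TransformerMixin):
    """Map spectra rows to a (n_samples, 3) array of [mode, mean, fwhm].

    Rows of ``X`` are baseline-corrected intensity traces on the shared
    ``shift`` axis (typically the output of
    :class:`~ramanprobe.preprocess.RamanPreprocessor`).
    """

    def __init__(self, shift=None, baseline_window=(2000.0, 2300.0), peak_window=(2100.0, 2130.0)):
        self.shift = shift
        self.baseline_window = baseline_window
        self.peak_window = peak_window

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_features=8)
        if self.shift is None:
            raise ValueError("PeakStatsExtractor requires the shared shift axis")
        if np.asarray(self.shift).size != X.shape[1]:
            raise ValueError("axis length does not match X")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = check_array(X)
        windows = AnalysisWindows(tuple(self.baseline_window), tuple(self.peak_window))
        shift = np.asarray(self.shift, dtype=float)
        out = np.empty((X.shape[0], 3))
        for i, row in enumerate(X):
            spec = Spectrum(shift=shift, intensity=row)
            stats = summarize(spec, windows)
            out[i] = (stats.mode, stats.mean, stats.fwhm)
        return out

    def get_feature_names_out(self, input_features=None):
        return np.asarray(["mode_cm1", "mean_cm1", "fwhm_cm1"], dtype=object)
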