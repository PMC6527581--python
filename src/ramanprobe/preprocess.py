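"""Reduce exposure stacks to baseline-corrected, peak-normalized spectra.

The default chain mirrors the standard workflow for sharp vibrational bands on
a broad background: co-add the repeated exposures, fit the surrounding
baseline region (2000-2300 cm^-1) with a seventh-degree polynomial after
cutting a hole over the band of interest (2100-2130 cm^-1), subtract the
polynomial, and scale the corrected trace so the maximum point of the band is
exactly 1.0.

The polynomial is fit on an axis mapped to [-1, 1] over the baseline window; a
raw-axis Vandermonde at ~2000-2300 raised to the 7th power is numerically
hostile, and the conditioning changes nothing mathematically. Window endpoints
are inclusive; points exactly at a mask edge belong to the mask (excluded from
the baseline fit, included in peak statistics).

An optional cross-exposure despike step removes single-point cosmic-ray
outliers before co-addition; it is off in the default chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .spectra import AxisMismatchError, ExposureStack, Spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisWindows",
    "BaselineFit",
    "coadd",
    "despike",
    "fit_baseline",
    "subtract_baseline",
    "normalize_peak",
    "preprocess_stack",
    "RamanPreprocessor",
]


@dataclass(frozen=True)
class AnalysisWindows:
    """Closed analysis intervals in cm^-1.

    ``baseline`` is the region used to establish the background; ``peak`` is
    the hole cut over the band (excluded from the baseline fit) and the window
    over which peak statistics are computed. ``peak`` must lie strictly inside
    ``baseline``.
    """

    baseline: tuple = (2000.0, 2300.0)
    peak: tuple = (2100.0, 2130.0)

    def __post_init__(self) -> None:
        blo, bhi = self.baseline
        plo, phi = self.peak
        if bhi <= blo or phi <= plo:
            raise ValueError("window endpoints must be ordered")
        if not (blo < plo and phi < bhi):
            raise ValueError("peak window must lie strictly inside the baseline window")

    def in_baseline(self, shift: np.ndarray) -> np.ndarray:
        blo, bhi = self.baseline
        return (shift >= blo) & (shift <= bhi)

    def in_peak(self, shift: np.ndarray) -> np.ndarray:
        plo, phi = self.peak
        return (shift >= plo) & (shift <= phi)


DEFAULT_WINDOWS = AnalysisWindows()


def coadd(stack: ExposureStack, mode: str = "mean") -> Spectrum:
    """Co-add the exposures of a stack pointwise (mean by default, or sum).

    The mean keeps the counts scale comparable across different accumulation
    times; metadata records the number of exposures and the mode used.
    """
    if mode not in ("mean", "sum"):
        raise ValueError(f"unknown coadd mode {mode!r}")
    data = stack.exposures.mean(axis=0) if mode == "mean" else stack.exposures.sum(axis=0)
    meta = dict(stack.meta)
    meta.update(n_exposures=stack.n_exposures, coadd_mode=mode)
    return Spectrum(
        shift=stack.shift.copy(),
        intensity=data,
        sample_id=stack.sample_id,
        probe=stack.probe,
        sample_class=stack.sample_class,
        meta=meta,
    )


def despike(stack: ExposureStack, z_thresh: float = 8.0) -> ExposureStack:
    """Replace single-exposure outliers by the cross-exposure median.

    A point is an outlier when it deviates from the per-point median across
    exposures by more than ``z_thresh`` robust standard deviations
    (1.4826 * MAD). The per-point MAD is itself noisy for small stacks, so it
    is smoothed along the axis with a width-15 median filter — the counting
    noise scale varies slowly with the mean signal, a single-point spike does
    not. Needs >= 3 exposures; with fewer the stack is passed through
    unchanged with a warning.
    """
    from scipy.signal import medfilt

    if z_thresh <= 0:
        raise ValueError("z_thresh must be positive")
    if stack.n_exposures < 3:
        logger.warning(
            "despike needs >= 3 exposures (got %d); passing through", stack.n_exposures
        )
        return stack
    med = np.median(stack.exposures, axis=0)
    mad = np.median(np.abs(stack.exposures - med), axis=0)
    robust_sd = 1.4826 * medfilt(mad, kernel_size=min(15, 2 * (stack.shift.size // 2) - 1))
    # floor avoids flagging identical exposures; a genuine spike still exceeds it
    floor = 1e-12 * max(1.0, float(np.max(np.abs(med))))
    robust_sd = np.maximum(robust_sd, floor)
    outliers = np.abs(stack.exposures - med) > z_thresh * robust_sd
    n = int(outliers.sum())
    if n:
        logger.info("despike: replaced %d outlier points", n)
    cleaned = np.where(outliers, np.broadcast_to(med, stack.exposures.shape), stack.exposures)
    meta = dict(stack.meta)
    meta["despiked_points"] = n
    return ExposureStack(
        shift=stack.shift.copy(),
        exposures=cleaned,
        exposure_time=stack.exposure_time,
        sample_id=stack.sample_id,
        probe=stack.probe,
        sample_class=stack.sample_class,
        meta=meta,
    )


@dataclass
class BaselineFit:
    """A masked polynomial baseline fit.

    Coefficients are in ascending order on the axis mapped to [-1, 1] over the
    baseline window (``domain``); :meth:`evaluate` applies the same mapping, so
    evaluating over the fit window reproduces the subtracted baseline exactly.
    """

    degree: int
    coeffs: np.ndarray
    windows: AnalysisWindows
    domain: tuple  # (lo, hi) of the conditioning map
    residual_rms: float
    n_fit_points: int
    fit_axis: np.ndarray = field(repr=False)  # axis points inside the baseline window

    def evaluate(self, shift) -> np.ndarray:
        lo, hi = self.domain
        x = 2.0 * (np.asarray(shift, dtype=float) - lo) / (hi - lo) - 1.0
        return np.polynomial.polynomial.polyval(x, self.coeffs)


def fit_baseline(
    spec: Spectrum, windows: AnalysisWindows = DEFAULT_WINDOWS, degree: int = 7
) -> BaselineFit:
    """Fit the baseline region, excluding the peak-window hole.

    Least-squares polynomial of the given degree over points inside the
    baseline window but outside the peak window, on the conditioned axis.
    """
    if degree < 0:
        raise ValueError("degree must be non-negative")
    blo, bhi = windows.baseline
    if spec.shift[0] > blo or spec.shift[-1] < bhi:
        raise ValueError(
            f"spectrum [{spec.shift[0]}, {spec.shift[-1]}] does not cover the "
            f"baseline window [{blo}, {bhi}]"
        )
    in_base = windows.in_baseline(spec.shift)
    fit_mask = in_base & ~windows.in_peak(spec.shift)
    n_fit = int(fit_mask.sum())
    if n_fit <= degree + 1:
        raise ValueError(
            f"only {n_fit} unmasked baseline points for a degree-{degree} fit"
        )
    x = 2.0 * (spec.shift[fit_mask] - blo) / (bhi - blo) - 1.0
    y = spec.intensity[fit_mask]
    vand = np.polynomial.polynomial.polyvander(x, degree)
    coeffs, _, rank, _ = np.linalg.lstsq(vand, y, rcond=None)
    if rank < degree + 1:
        raise ValueError(f"rank-deficient baseline fit (rank {rank} < {degree + 1})")
    resid = y - vand @ coeffs
    rms = float(np.sqrt(np.mean(resid**2)))
    logger.debug("baseline fit: degree=%d n=%d residual_rms=%.4g", degree, n_fit, rms)
    return BaselineFit(
        degree=degree,
        coeffs=coeffs,
        windows=windows,
        domain=(blo, bhi),
        residual_rms=rms,
        n_fit_points=n_fit,
        fit_axis=spec.shift[in_base].copy(),
    )


def subtract_baseline(spec: Spectrum, fit: BaselineFit) -> Spectrum:
    """Subtract a fitted baseline; output restricted to the baseline window.

    Negative post-subtraction intensities are preserved — clipping before
    normalization would bias the centroid; the statistics layer clips only
    inside its weights.
    """
    in_base = fit.windows.in_baseline(spec.shift)
    axis = spec.shift[in_base]
    if axis.size != fit.fit_axis.size or np.any(np.abs(axis - fit.fit_axis) > 1e-9):
        raise AxisMismatchError("spectrum axis differs from the axis the baseline was fit on")
    corrected = spec.intensity[in_base] - fit.evaluate(axis)
    out = spec.replace(shift=axis, intensity=corrected, normalized=False)
    out.meta["baseline_degree"] = fit.degree
    out.meta["baseline_residual_rms"] = fit.residual_rms
    return out


def normalize_peak(spec: Spectrum, windows: AnalysisWindows = DEFAULT_WINDOWS) -> Spectrum:
    """Scale so the maximum point inside the peak window is exactly 1.0."""
    in_peak = windows.in_peak(spec.shift)
    if not in_peak.any():
        raise ValueError("no points inside the peak window")
    peak_max = float(spec.intensity[in_peak].max())
    if peak_max <= 0:
        raise ValueError("non-positive maximum in the peak window: no detectable band")
    out = spec.replace(intensity=spec.intensity / peak_max, normalized=True)
    out.meta["normalization_factor"] = peak_max
    return out


def preprocess_stack(
    stack: ExposureStack,
    windows: AnalysisWindows = DEFAULT_WINDOWS,
    degree: int = 7,
    coadd_mode: str = "mean",
    do_despike: bool = False,
    z_thresh: float = 8.0,
) -> tuple[Spectrum, BaselineFit]:
    """Full chain: (despike) -> coadd -> fit/subtract baseline -> normalize."""
    if do_despike:
        stack = despike(stack, z_thresh=z_thresh)
    spec = coadd(stack, mode=coadd_mode)
    fit = fit_baseline(spec, windows=windows, degree=degree)
    corrected = subtract_baseline(spec, fit)
    return normalize_peak(corrected, windows=windows), fit


class RamanPreprocessor(BaseEstimator, TransformerMixin):
    """Baseline-correct and peak-normalize spectra, sklearn-transformer style.

    Rows of ``X`` are intensity traces on the shared ``shift`` axis. The
    transform restricts each row to the baseline window, subtracts a masked
    polynomial baseline fitted per row, and scales the band maximum to 1.0.
    The transform is stateless per row (nothing is learned across samples);
    ``fit`` validates the axis and windows.

    Parameters
    ----------
    shift : array-like
        Shared Raman shift axis for all rows of ``X``.
    baseline_window, peak_window : tuple of float
        Closed intervals in cm^-1; peak strictly inside baseline.
    degree : int
        Baseline polynomial degree.
    normalize : bool
        Scale the band maximum to 1.0 after subtraction.

    Attributes
    ----------
    shift_out_ : ndarray
        Axis of the transformed rows (input axis restricted to the baseline
        window).
    n_features_in_ : int
    """

    def __init__(
        self,
        shift=None,
        baseline_window=(2000.0, 2300.0),
        peak_window=(2100.0, 2130.0),
        degree=7,
        normalize=True,
    ):
        self.shift = shift
        self.baseline_window = baseline_window
        self.peak_window = peak_window
        self.degree = degree
        self.normalize = normalize

    def _windows(self) -> AnalysisWindows:
        return AnalysisWindows(tuple(self.baseline_window), tuple(self.peak_window))

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_features=8)
        if self.shift is None:
            raise ValueError("RamanPreprocessor requires the shared shift axis")
        shift = np.asarray(self.shift, dtype=float)
        if shift.size != X.shape[1]:
            raise ValueError(f"axis has {shift.size} points but X has {X.shape[1]} features")
        windows = self._windows()
        self.n_features_in_ = X.shape[1]
        self.shift_out_ = shift[windows.in_baseline(shift)].copy()
        return self

    def transform(self, X):
        check_is_fitted(self, "shift_out_")
        X = check_array(X)
        shift = np.asarray(self.shift, dtype=float)
        windows = self._windows()
        out = np.empty((X.shape[0], self.shift_out_.size))
        for i, row in enumerate(X):
            spec = Spectrum(shift=shift, intensity=row)
            fit = fit_baseline(spec, windows=windows, degree=self.degree)
            corrected = subtract_baseline(spec, fit)
            if self.normalize:
                corrected = normalize_peak(corrected, windows=windows)
            out[i] = corrected.intensity
        return out
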