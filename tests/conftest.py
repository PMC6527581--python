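import numpy as np
import pytest

from ramanprobe import AnalysisWindows, ProbeModel, Spectrum, make_axis, pseudo_voigt


@pytest.fixture
def axis():
    """Default 1950-2350 cm^-1 axis at 1 cm^-1 step."""
    return make_axis()


@pytest.fixture
def windows():
    return AnalysisWindows()


@pytest.fixture
def model():
    return ProbeModel()


@pytest.fixture
def band_spectrum(axis):
    """Factory for a noise-free, baseline-free band spectrum on the axis."""

    def make(center=2118.0, fwhm=14.0, eta=0.5, amplitude=1.0, normalized=True, **kwargs):
        intensity = amplitude * pseudo_voigt(axis, center, fwhm, eta)
        return Spectrum(shift=axis, intensity=intensity, normalized=normalized, **kwargs)

    return make
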