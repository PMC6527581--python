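"""Synthetic alkyne-band Raman spectra with recorded ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a two-state pseudo-Voigt alkyne C#C band — an aqueous component at
``nu_aq`` and a sequestered component shifted to higher frequency by
``delta_seq`` — sitting on a smooth low-order polynomial baseline, acquired as
repeated short exposures with Poisson-like counting noise. Every simulated
dataset carries a :class:`GroundTruth` so downstream estimators can be scored
against the fraction of the probe population that is sequestered.

Defaults place the band at 2118 cm^-1 with a +6 cm^-1 sequestration shift on a
1950-2350 cm^-1 axis; they are synthetic working values for a band "close to
2100 cm^-1", not measurements.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from typing import NamedTuple

import numpy as np

from .spectra import ExposureStack

logger = logging.getLogger(__name__)

__all__ = [
    "ProbeModel",
    "GroundTruth",
    "AxisSpec",
    "Scenario",
    "pseudo_voigt",
    "make_axis",
    "band_profile",
    "baseline_profile",
    "simulate_spectrum",
    "simulate_reference",
    "scenario_suite",
    "DEFAULT_AXIS",
    "DEFAULT_BASELINE_COEFFS",
]

#: Default axis: covers the 2000-2300 cm^-1 analysis region with margin.
DEFAULT_AXIS = (1950.0, 2350.0, 1.0)

#: Default baseline polynomial (ascending coefficients on the [-1, 1] scaled
#: axis); gentle, strictly positive over the axis, well inside degree 7.
DEFAULT_BASELINE_COEFFS = (220.0, -35.0, 25.0, -8.0)


class AxisSpec(NamedTuple):
    """Sampling of the Raman shift axis, all in cm^-1."""

    min: float
    max: float
    step: float


def make_axis(axis_spec=DEFAULT_AXIS) -> np.ndarray:
    lo, hi, step = AxisSpec(*axis_spec)
    if step <= 0:
        raise ValueError("axis step must be positive")
    if hi <= lo:
        raise ValueError("axis max must exceed min")
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def pseudo_voigt(x, center: float, fwhm: float, eta: float) -> np.ndarray:
    """Unit-peak-height pseudo-Voigt: (1-eta) Gaussian + eta Lorentzian.

    Both components share the same FWHM, so the profile's full width at half
    maximum is ``fwhm`` for every mixing fraction ``eta`` in [0, 1].
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    if not 0.0 <= eta <= 1.0:
        raise ValueError("eta must lie in [0, 1]")
    u = (np.asarray(x, dtype=float) - center) / fwhm
    gauss = np.exp(-4.0 * np.log(2.0) * u * u)
    lorentz = 1.0 / (1.0 + 4.0 * u * u)
    return (1.0 - eta) * gauss + eta * lorentz


@dataclass
class ProbeModel:
    """Two-state band model for one alkyne probe.

    ``nu_aq`` is the aqueous (non-sequestered) band center; the sequestered
    component sits at ``nu_aq + delta_seq`` (positive shift = more hydrophobic
    environment) and is typically narrower (less inhomogeneous broadening
    inside the protein cavity). ``amplitude`` is the peak height in counts.
    """

    nu_aq: float = 2118.0
    delta_seq: float = 6.0
    width_aq: float = 14.0
    width_seq: float = 10.0
    eta: float = 0.5
    amplitude: float = 1000.0
    #: window within which both band centers must lie (analysis peak window)
    peak_window: tuple = (2100.0, 2130.0)

    def __post_init__(self) -> None:
        if self.width_aq <= 0 or self.width_seq <= 0:
            raise ValueError("band widths must be positive")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")
        lo, hi = self.peak_window
        for name, nu in (("nu_aq", self.nu_aq), ("nu_aq+delta_seq", self.nu_aq + self.delta_seq)):
            if not lo <= nu <= hi:
                raise ValueError(f"{name} = {nu} lies outside the peak window [{lo}, {hi}]")


@dataclass
class GroundTruth:
    """Everything needed to regenerate a simulated dataset bit for bit."""

    fraction_sequestered: float = 0.0
    baseline_coeffs: tuple = DEFAULT_BASELINE_COEFFS
    noise_scale: float = 1.0
    seed: int = 0
    cosmic_ray_rate: float = 0.0  # expected spikes per exposure; default off
    cosmic_ray_height: float = 5e4  # counts added at a spiked point

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_sequestered <= 1.0:
            raise ValueError("fraction_sequestered must lie in [0, 1]")
        self.baseline_coeffs = tuple(float(c) for c in self.baseline_coeffs)
        if len(self.baseline_coeffs) > 8:
            raise ValueError("baseline polynomial degree must be <= 7")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")
        self.seed = int(self.seed)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


def band_profile(axis: np.ndarray, model: ProbeModel, fraction: float) -> np.ndarray:
    """Noise-free band: amplitude * [(1-f) V_aq + f V_seq]."""
    aq = pseudo_voigt(axis, model.nu_aq, model.width_aq, model.eta)
    seq = pseudo_voigt(axis, model.nu_aq + model.delta_seq, model.width_seq, model.eta)
    return model.amplitude * ((1.0 - fraction) * aq + fraction * seq)


def baseline_profile(axis: np.ndarray, coeffs) -> np.ndarray:
    """Evaluate baseline coefficients given on the axis scaled to [-1, 1]."""
    lo, hi = axis[0], axis[-1]
    x = 2.0 * (axis - lo) / (hi - lo) - 1.0
    return np.polynomial.polynomial.polyval(x, np.asarray(coeffs, dtype=float))


def simulate_spectrum(
    model: ProbeModel,
    truth: GroundTruth,
    axis_spec=DEFAULT_AXIS,
    n_exposures: int = 30,
    sample_id: str = "sim",
    probe: str = "C8",
    sample_class: str = "probe_on_protein",
) -> tuple[ExposureStack, GroundTruth]:
    """Simulate an exposure stack for the given model and ground truth.

    Each exposure is ``baseline + band + noise`` where the noise is an
    independent Gaussian approximation to Poisson counting noise
    (sigma = noise_scale * sqrt(mean counts) per point). Deterministic for a
    fixed ``truth.seed``.
    """
    if n_exposures < 1:
        raise ValueError("n_exposures must be >= 1")
    axis = make_axis(axis_spec)
    mean = baseline_profile(axis, truth.baseline_coeffs) + band_profile(
        axis, model, truth.fraction_sequestered
    )
    rng = np.random.default_rng(truth.seed)
    sigma = truth.noise_scale * np.sqrt(np.clip(mean, 0.0, None))
    exposures = mean + sigma * rng.standard_normal((n_exposures, axis.size))
    if truth.cosmic_ray_rate > 0:
        hits = rng.random((n_exposures, axis.size)) < (truth.cosmic_ray_rate / axis.size)
        exposures = exposures + truth.cosmic_ray_height * hits
        logger.info("injected %d cosmic-ray spikes", int(hits.sum()))
    stack = ExposureStack(
        shift=axis,
        exposures=exposures,
        sample_id=sample_id,
        probe=probe,
        sample_class=sample_class,
        meta={"fraction_sequestered": truth.fraction_sequestered, "seed": truth.seed},
    )
    return stack, truth


def simulate_reference(
    model: ProbeModel,
    axis_spec=DEFAULT_AXIS,
    n_exposures: int = 30,
    seed: int = 0,
    noise_scale: float = 1.0,
    baseline_coeffs=DEFAULT_BASELINE_COEFFS,
    sample_id: str = "reference",
    probe: str = "C8",
) -> ExposureStack:
    """Simulate a free-probe reference: the same model with f forced to 0."""
    truth = GroundTruth(
        fraction_sequestered=0.0,
        baseline_coeffs=baseline_coeffs,
        noise_scale=noise_scale,
        seed=seed,
    )
    stack, _ = simulate_spectrum(
        model,
        truth,
        axis_spec=axis_spec,
        n_exposures=n_exposures,
        sample_id=sample_id,
        probe=probe,
        sample_class="free_probe",
    )
    return stack


@dataclass
class Scenario:
    """One labeled simulation: sample stack, paired reference, ground truth."""

    name: str
    stack: ExposureStack
    reference: ExposureStack
    truth: GroundTruth


def scenario_suite(
    seed: int,
    model: ProbeModel | None = None,
    axis_spec=DEFAULT_AXIS,
    n_exposures: int = 30,
    noise_scale: float = 1.0,
) -> list[Scenario]:
    """The three canonical sequestration scenarios.

    * ``sequestered`` (f = 1): the probe frequency shifts fully to the
      hydrophobic position — the behavior of a chain buried in the cavity.
    * ``not_sequestered`` (f = 0): sample indistinguishable in distribution
      from the free-probe reference.
    * ``partial`` (f = 0.5): both environments populated; the band broadens
      and covers both frequencies rather than resolving two peaks
      (delta_seq is smaller than the component widths by default).
    """
    model = model or ProbeModel()
    master = np.random.default_rng(seed)
    seeds = master.integers(0, 2**31 - 1, size=6)
    fractions = {"sequestered": 1.0, "not_sequestered": 0.0, "partial": 0.5}
    scenarios = []
    for i, (name, f) in enumerate(fractions.items()):
        truth = GroundTruth(
            fraction_sequestered=f,
            noise_scale=noise_scale,
            seed=int(seeds[2 * i]),
        )
        stack, truth = simulate_spectrum(
            model,
            truth,
            axis_spec=axis_spec,
            n_exposures=n_exposures,
            sample_id=f"scenario_{name}",
        )
        reference = simulate_reference(
            model,
            axis_spec=axis_spec,
            n_exposures=n_exposures,
            seed=int(seeds[2 * i + 1]),
            noise_scale=noise_scale,
            sample_id=f"reference_{name}",
        )
        scenarios.append(Scenario(name=name, stack=stack, reference=reference, truth=truth))
    return scenarios
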