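"""Mass verification for probe loading onto carrier proteins.

Carrier proteins occur as *apo* (bare conserved serine), *holo* (with the
4'-phosphopantetheine arm attached), and *acyl* (a substrate thioesterified
onto the arm's terminal thiol). Loading is verified by intact-protein ESI-MS:
the observed molecular weight is compared with the calculated one for the
holo- and acyl- species, after deconvoluting the multiply-protonated
charge-state series.

Mass arithmetic:

* holo = apo + Ppant (C11H21N2O6PS, monoisotopic 340.0858 Da),
* acyl = holo + acid - H2O (thioester condensation).

The alkyne probes are 4-pentynoic acid (C5, C5H6O2), 7-octynoic acid
(C8, C8H12O2) and 12-tridecynoic acid (C13, C13H22O2).

Residue and elemental masses come from pyteomics. Intact-protein comparisons
default to the average mass (a deconvoluted intact MW is an average-mass
quantity); monoisotopic is supported throughout. N-terminal Met processing is
not modeled and His tags are not auto-appended — supply the mature construct
sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from pyteomics import mass as _pmass

logger = logging.getLogger(__name__)

__all__ = [
    "PROTON_MASS",
    "PPANT_FORMULA",
    "WATER_FORMULA",
    "PROBE_FORMULAS",
    "protein_mass",
    "formula_mass",
    "modification_shift",
    "ProteinSpecies",
    "ChargeSeries",
    "deconvolute_series",
    "verify_loading",
    "LoadingCheck",
    "species_from_fasta",
]

PROTON_MASS = 1.007276  # Da
PPANT_FORMULA = "C11H21N2O6PS"
WATER_FORMULA = "H2O"

#: Terminal-alkyne fatty-acid probes, by carbon count.
PROBE_FORMULAS = {
    "C5": "C5H6O2",  # 4-pentynoic acid
    "C8": "C8H12O2",  # 7-octynoic acid
    "C13": "C13H22O2",  # 12-tridecynoic acid
}

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


def _check_scale(scale: str) -> bool:
    if scale not in ("average", "monoisotopic"):
        raise ValueError(f"scale must be 'average' or 'monoisotopic', got {scale!r}")
    return scale == "average"


def protein_mass(sequence: str, scale: str = "average") -> float:
    """Mass in Da of an intact protein from its one-letter sequence.

    Sum of residue masses plus one water; only the 20 standard residues are
    accepted (an invalid character raises, naming its position).
    """
    average = _check_scale(scale)
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    for i, ch in enumerate(seq):
        if ch not in _STANDARD_AA:
            raise ValueError(f"invalid residue {ch!r} at position {i + 1}")
    return float(_pmass.calculate_mass(sequence=seq, average=average))


def formula_mass(formula: str, scale: str = "average") -> float:
    """Mass in Da of a molecular formula (e.g. ``C11H21N2O6PS``)."""
    average = _check_scale(scale)
    return float(_pmass.calculate_mass(formula=formula, average=average))


def modification_shift(
    transition: str,
    scale: str = "average",
    probe: str | None = None,
    formula: str | None = None,
) -> float:
    """Mass added by a modification-state transition.

    ``apo_to_holo`` adds the phosphopantetheinyl group; ``holo_to_acyl`` adds
    the acid (named probe or explicit ``formula``) minus water for the
    thioester bond.
    """
    if transition == "apo_to_holo":
        return formula_mass(PPANT_FORMULA, scale)
    if transition == "holo_to_acyl":
        if formula is None:
            if probe is None:
                raise ValueError("holo_to_acyl needs a probe name or an acid formula")
            try:
                formula = PROBE_FORMULAS[probe]
            except KeyError:
                raise ValueError(
                    f"unknown probe {probe!r}; known: {sorted(PROBE_FORMULAS)} "
                    "(or pass an explicit formula)"
                ) from None
        return formula_mass(formula, scale) - formula_mass(WATER_FORMULA, scale)
    raise ValueError(f"unknown transition {transition!r}")


@dataclass
class ProteinSpecies:
    """A carrier protein in a defined modification state with expected mass."""

    identifier: str
    sequence: str
    state: str = "apo"  # apo | holo | acyl
    probe: str | None = None
    acid_formula: str | None = None

    def __post_init__(self) -> None:
        if self.state not in ("apo", "holo", "acyl"):
            raise ValueError(f"unknown state {self.state!r}")
        if self.state == "acyl" and self.probe is None and self.acid_formula is None:
            raise ValueError("acyl species needs a probe name or acid formula")
        protein_mass(self.sequence, "monoisotopic")  # validates the sequence
        logger.debug(
            "%s: N-terminal Met processing is not modeled; sequence taken as mature",
            self.identifier,
        )

    def expected_mass(self, scale: str = "average") -> float:
        m = protein_mass(self.sequence, scale)
        if self.state in ("holo", "acyl"):
            m += modification_shift("apo_to_holo", scale)
        if self.state == "acyl":
            m += modification_shift(
                "holo_to_acyl", scale, probe=self.probe, formula=self.acid_formula
            )
        return m


@dataclass
class ChargeSeries:
    """A deconvoluted consecutive charge-state series."""

    mz: np.ndarray  # ascending observed m/z (Th)
    charges: np.ndarray  # assigned positive charges, one per peak
    peak_masses: np.ndarray  # per-peak neutral mass estimates (Da)
    mass: float  # mean of peak_masses
    sd: float  # standard deviation across peaks
    ambiguous: bool = False  # a competing assignment scored within 2x of best
    warning: bool = False  # best sd above the sanity bound

    def __post_init__(self) -> None:
        if len(self.mz) < 2:
            raise ValueError("a charge series needs >= 2 peaks")


def deconvolute_series(
    mz_peaks: Sequence[float],
    charge_range: tuple[int, int] = (1, 60),
    sanity_sd: float = 2.0,
) -> ChargeSeries:
    """Deconvolute consecutive positive-mode charge states to a neutral mass.

    The peaks are assumed to be consecutive protonated charge states of one
    species: higher charge at lower m/z. For each candidate charge of the
    highest-m/z peak, per-peak masses are ``z * (m/z - m_proton)``; the
    assignment minimizing the standard deviation across peaks wins (the
    consistency criterion used by charge-deconvolution tools for intact
    proteins). The reported mass is the mean of the per-peak estimates.
    """
    mz = np.asarray(list(mz_peaks), dtype=float)
    if mz.size < 2:
        raise ValueError("need at least 2 peaks to resolve the charge states")
    if np.any(np.diff(mz) <= 0):
        raise ValueError("m/z peaks must be strictly ascending")
    z_min, z_max = charge_range
    if z_min < 1 or z_max < z_min:
        raise ValueError("invalid charge range")

    n = mz.size
    candidates = []
    for z_top in range(z_min, z_max + 1):  # charge of the highest-m/z peak
        # ascending m/z <-> descending charge
        charges = z_top + np.arange(n - 1, -1, -1)
        if charges.max() > z_max:
            continue
        masses = charges * (mz - PROTON_MASS)
        sd = float(np.std(masses, ddof=1))
        candidates.append((sd, charges, masses))
    if not candidates:
        raise ValueError("no admissible charge assignment in the given range")
    candidates.sort(key=lambda c: c[0])
    best_sd, charges, masses = candidates[0]
    ambiguous = len(candidates) > 1 and candidates[1][0] <= 2.0 * max(best_sd, 1e-12)
    warning = best_sd > sanity_sd
    if warning:
        logger.warning(
            "deconvolution: best assignment SD %.3g Da exceeds sanity bound %.3g Da",
            best_sd,
            sanity_sd,
        )
    return ChargeSeries(
        mz=mz,
        charges=charges,
        peak_masses=masses,
        mass=float(masses.mean()),
        sd=best_sd,
        ambiguous=ambiguous,
        warning=warning,
    )


class LoadingCheck(NamedTuple):
    match: bool
    delta: float  # observed - expected, Da
    expected: float
    observed: float


def verify_loading(
    species: ProteinSpecies,
    observed_mass: float,
    tolerance: float = 1.0,
    scale: str = "average",
) -> LoadingCheck:
    """Compare an observed deconvoluted MW with the calculated species mass."""
    expected = species.expected_mass(scale)
    delta = observed_mass - expected
    match = abs(delta) <= tolerance
    logger.info(
        "%s (%s): expected %.2f observed %.2f delta %+.2f -> %s",
        species.identifier,
        species.state,
        expected,
        observed_mass,
        delta,
        "match" if match else "mismatch",
    )
    return LoadingCheck(match=match, delta=float(delta), expected=float(expected), observed=float(observed_mass))


def species_from_fasta(
    path, state: str = "apo", probe: str | None = None
) -> list[ProteinSpecies]:
    """Read protein sequences from a FASTA file as species in one state."""
    from Bio import SeqIO

    species = []
    for record in SeqIO.parse(str(path), "fasta"):
        species.append(
            ProteinSpecies(
                identifier=record.id,
                sequence=str(record.seq),
                state=state,
                probe=probe,
            )
        )
    if not species:
        raise ValueError(f"no FASTA records in {path}")
    return species
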