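"""Mass arithmetic and charge-series deconvolution.

The formula-mass oracle here is an independent atomic-mass-sum over a local
table of IUPAC monoisotopic masses, deliberately separate from the
implementation's mass backend.
"""

import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ramanprobe import (
    ProteinSpecies,
    deconvolute_series,
    formula_mass,
    modification_shift,
    protein_mass,
    species_from_fasta,
    verify_loading,
)
from ramanprobe.masscheck import PROBE_FORMULAS, PROTON_MASS

# independent oracle: IUPAC monoisotopic atomic masses
MONO = {"C": 12.0, "H": 1.00782503, "N": 14.00307401, "O": 15.99491462,
        "P": 30.97376200, "S": 31.97207117}


def oracle_mono(formula: str) -> float:
    total = 0.0
    for element, count in re.findall(r"([A-Z][a-z]?)(\d*)", formula):
        if element:
            total += MONO[element] * (int(count) if count else 1)
    return total


class TestProteinMass:
    def test_single_glycine_free_amino_acid(self):
        assert protein_mass("G", "monoisotopic") == pytest.approx(75.0320, abs=0.001)

    def test_diglycine_residue_sum(self):
        # 2 glycine residues + one water
        assert protein_mass("GG", "monoisotopic") == pytest.approx(132.0535, abs=0.001)

    def test_empty_sequence_error(self):
        with pytest.raises(ValueError, match="empty"):
            protein_mass("")

    def test_invalid_residue_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            protein_mass("GGXGG")

    @pytest.mark.parametrize("seq", ["ACDEFGHIKLMNPQRSTVWY", "MKTAYIAKQR", "G"])
    def test_average_at_least_monoisotopic(self, seq):
        assert protein_mass(seq, "average") >= protein_mass(seq, "monoisotopic")


class TestModificationShift:
    def test_ppant_shift_vs_atomic_oracle(self):
        got = modification_shift("apo_to_holo", "monoisotopic")
        assert got == pytest.approx(oracle_mono("C11H21N2O6PS"), abs=0.001)
        assert got == pytest.approx(340.0858, abs=0.001)

    def test_c8_acyl_shift_vs_atomic_oracle(self):
        got = modification_shift("holo_to_acyl", "monoisotopic", probe="C8")
        assert got == pytest.approx(oracle_mono("C8H12O2") - oracle_mono("H2O"), abs=0.001)
        assert got == pytest.approx(122.0732, abs=0.001)

    def test_c5_vs_c13_differ_by_eight_methylenes(self):
        c5 = modification_shift("holo_to_acyl", "monoisotopic", probe="C5")
        c13 = modification_shift("holo_to_acyl", "monoisotopic", probe="C13")
        ch2 = oracle_mono("CH2")
        assert c13 - c5 == pytest.approx(8 * ch2, abs=0.001)
        assert c13 - c5 == pytest.approx(8 * 14.0157, abs=0.001)

    def test_unknown_probe_without_formula_error(self):
        with pytest.raises(ValueError, match="unknown probe"):
            modification_shift("holo_to_acyl", probe="C99")

    def test_explicit_formula_accepted(self):
        got = modification_shift("holo_to_acyl", "monoisotopic", formula="C6H8O2")
        assert got == pytest.approx(oracle_mono("C6H8O2") - oracle_mono("H2O"), abs=0.001)


class TestSpecies:
    SEQ = "MSTIEERVKKIIGEQLGVKQEEVTNNASFVEDLGADSLDTVELVMALEEEFDTEIPDEEAEKITTVQAAIDYINGHQA"

    def test_mass_additivity_exact_for_every_probe(self):
        for scale in ("average", "monoisotopic"):
            apo = ProteinSpecies("acp", self.SEQ, "apo").expected_mass(scale)
            holo = ProteinSpecies("acp", self.SEQ, "holo").expected_mass(scale)
            for probe in PROBE_FORMULAS:
                acyl = ProteinSpecies("acp", self.SEQ, "acyl", probe=probe).expected_mass(scale)
                expected = (
                    apo
                    + modification_shift("apo_to_holo", scale)
                    + modification_shift("holo_to_acyl", scale, probe=probe)
                )
                assert acyl == pytest.approx(expected, abs=1e-9)
                assert holo - apo == pytest.approx(
                    modification_shift("apo_to_holo", scale), abs=1e-9
                )

    def test_acyl_needs_probe(self):
        with pytest.raises(ValueError):
            ProteinSpecies("x", "GG", "acyl")

    def test_verify_loading_distinguishes_holo_from_acyl(self):
        holo = ProteinSpecies("acp", self.SEQ, "holo")
        acyl = ProteinSpecies("acp", self.SEQ, "acyl", probe="C8")
        observed = acyl.expected_mass("average")
        assert verify_loading(acyl, observed).match
        check = verify_loading(holo, observed)
        assert not check.match
        assert check.delta == pytest.approx(
            modification_shift("holo_to_acyl", "average", probe="C8"), abs=1e-9
        )

    def test_exact_match_and_zero_tolerance(self):
        sp = ProteinSpecies("acp", self.SEQ, "apo")
        expected = sp.expected_mass()
        assert verify_loading(sp, expected) == (True, 0.0, expected, expected)
        assert not verify_loading(sp, expected + 1e-6, tolerance=0.0).match


class TestDeconvolution:
    @staticmethod
    def series(mass, charges):
        return sorted((mass + z * PROTON_MASS) / z for z in charges)

    def test_exact_synthetic_series(self):
        mz = self.series(10000.0, range(8, 13))
        out = deconvolute_series(mz)
        assert out.mass == pytest.approx(10000.0, abs=0.01)
        assert out.sd < 0.01
        assert sorted(out.charges) == [8, 9, 10, 11, 12]

    def test_perturbed_series_stays_close(self):
        mz = [v + 0.05 for v in self.series(10000.0, range(8, 13))]
        out = deconvolute_series(mz)
        assert out.mass == pytest.approx(10000.0, abs=0.6)

    def test_two_peaks_exact(self):
        mz = self.series(12000.0, [9, 10])
        out = deconvolute_series(mz)
        assert out.mass == pytest.approx(12000.0, abs=0.01)

    def test_fewer_than_two_peaks_error(self):
        with pytest.raises(ValueError, match="2 peaks"):
            deconvolute_series([1000.0])

    def test_non_ascending_error(self):
        with pytest.raises(ValueError, match="ascending"):
            deconvolute_series([1200.0, 1100.0])

    def test_sanity_bound_sets_warning_flag(self):
        # peaks that are not a consistent series of anything
        out = deconvolute_series([900.0, 1000.0, 1300.0], sanity_sd=0.5)
        assert out.warning

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        mass=st.floats(5000.0, 25000.0),
        z_top=st.integers(5, 20),
        n=st.integers(3, 8),
    )
    def test_round_trip_property(self, mass, z_top, n):
        mz = self.series(mass, range(z_top, z_top + n))
        out = deconvolute_series(mz)
        assert out.mass == pytest.approx(mass, abs=0.01)


def test_species_from_fasta(tmp_path):
    p = tmp_path / "acp.fasta"
    p.write_text(">EcACP test construct\nMSTIEERVKKII\n>Second\nGGAAGG\n")
    species = species_from_fasta(p, state="holo")
    assert [sp.identifier for sp in species] == ["EcACP", "Second"]
    assert all(sp.state == "holo" for sp in species)
    assert species[1].expected_mass("monoisotopic") == pytest.approx(
        protein_mass("GGAAGG", "monoisotopic") + modification_shift("apo_to_holo", "monoisotopic"),
        abs=1e-9,
    )
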