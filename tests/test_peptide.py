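"""Sequence parsing, mass/charge arithmetic and physicochemical descriptors."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from oleopep.peptide import (
    PROTON_MASS,
    WATER_MONO_MASS,
    Peptide,
    PeptideParseError,
    ResidueClassConfig,
    cterm_rule,
    hydrophobic_fraction,
    monoisotopic_mass,
    parse_sequence,
    ppm_error,
    residue_census,
    theoretical_mz,
)

from conftest import sequences


class TestParse:
    @pytest.mark.parametrize(
        "text, seq, mods",
        [
            ("LLLGAGCM(+15.99)", "LLLGAGCM", {7: 15.99}),
            ("CPANGFY", "CPANGFY", {}),
            ("M(+15.99)AK", "MAK", {0: 15.99}),
            ("AM(−0.98)K", "AMK", {1: -0.98}),
        ],
    )
    def test_examples(self, text, seq, mods):
        p = parse_sequence(text)
        assert p.sequence == seq
        assert dict(p.modifications) == pytest.approx(mods)

    @pytest.mark.parametrize(
        "bad",
        ["", "M(+15.99)(+15.99)", "(+15.99)M", "ABZ", "A B"],
    )
    def test_malformed(self, bad):
        with pytest.raises(PeptideParseError):
            parse_sequence(bad)

    def test_error_names_position(self):
        with pytest.raises(PeptideParseError, match="position 2"):
            parse_sequence("ACX")

    @given(sequences)
    def test_round_trip_bare(self, seq):
        assert str(parse_sequence(seq)) == seq

    def test_round_trip_modified(self):
        text = "LLLGAGCM(+15.99)"
        assert str(parse_sequence(text)) == text

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            Peptide("AC", {5: 1.0})
        with pytest.raises(ValueError):
            Peptide("")


class TestMass:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("CPANGFY", 770.3057),
            ("G", 75.0320),
            ("LLLGAGCM(+15.99)", 792.3874),  # exact Met-oxidation delta applied
            ("CCYSVY", 736.2560),
            ("VCGEAFGKA", 880.4113),
            ("LDTANEMNQLDLQFR", 1806.8571),
        ],
    )
    def test_reference_masses(self, text, expected):
        assert monoisotopic_mass(parse_sequence(text)) == pytest.approx(
            expected, abs=1e-3
        )

    def test_nominal_delta_without_canonical_map(self):
        p = parse_sequence("LLLGAGCM(+15.99)")
        bare = monoisotopic_mass(parse_sequence("LLLGAGCM"))
        assert monoisotopic_mass(p, canonical_modifications=False) == pytest.approx(
            bare + 15.99
        )
        assert monoisotopic_mass(p) == pytest.approx(bare + 15.9949)

    @given(sequences, sequences)
    def test_mass_additivity(self, a, b):
        whole = monoisotopic_mass(Peptide(a + b))
        parts = monoisotopic_mass(Peptide(a)) + monoisotopic_mass(Peptide(b))
        assert whole == pytest.approx(parts - WATER_MONO_MASS, abs=1e-9)

    @given(sequences)
    def test_matches_pyteomics_oracle(self, seq):
        pyteomics_mass = pytest.importorskip("pyteomics.mass")
        assert monoisotopic_mass(Peptide(seq)) == pytest.approx(
            pyteomics_mass.calculate_mass(sequence=seq, monoisotopic=True), abs=1e-3
        )


class TestMz:
    def test_derived_examples(self):
        assert theoretical_mz(Peptide("CCYSVY"), 2) == pytest.approx(369.1353, abs=1e-3)
        assert theoretical_mz(Peptide("LDTANEMNQLDLQFR"), 2) == pytest.approx(
            904.4358, abs=1e-3
        )

    @given(sequences)
    def test_z1_identity(self, seq):
        p = Peptide(seq)
        assert theoretical_mz(p, 1) == pytest.approx(
            monoisotopic_mass(p) + PROTON_MASS
        )

    @given(sequences, st.integers(min_value=1, max_value=5))
    def test_strictly_decreasing_in_z(self, seq, z):
        p = Peptide(seq)
        assert theoretical_mz(p, z) > theoretical_mz(p, z + 1)

    def test_invalid_charge(self):
        with pytest.raises(ValueError):
            theoretical_mz(Peptide("AG"), 0)


class TestPpm:
    @given(sequences, st.integers(min_value=1, max_value=4))
    def test_zero_at_theoretical(self, seq, z):
        p = Peptide(seq)
        assert ppm_error(theoretical_mz(p, z), p, z) == pytest.approx(0.0, abs=1e-9)

    def test_definition(self):
        p = Peptide("CCYSVY")
        theo = theoretical_mz(p, 2)
        assert ppm_error(theo * (1 + 1e-6), p, 2) == pytest.approx(1.0, abs=1e-6)

    def test_observed_reference_value(self):
        # observed 369.1365 vs theoretical 369.1353 at z=2
        assert ppm_error(369.1365, Peptide("CCYSVY"), 2) == pytest.approx(3.3, abs=0.3)


class TestDescriptors:
    @pytest.mark.parametrize(
        "seq, frac",
        [("AAAA", 1.0), ("KKKK", 0.0), ("CCYSVY", 1 / 6)],
    )
    def test_hydrophobic_fraction(self, seq, frac):
        assert hydrophobic_fraction(Peptide(seq)) == pytest.approx(frac)

    @given(sequences, st.randoms(use_true_random=False))
    def test_fraction_permutation_invariant(self, seq, rnd):
        shuffled = list(seq)
        rnd.shuffle(shuffled)
        assert hydrophobic_fraction(Peptide("".join(shuffled))) == pytest.approx(
            hydrophobic_fraction(Peptide(seq))
        )

    @pytest.mark.parametrize(
        "seq, expected",
        [("VCGEAFGKA", True), ("GGGSSS", False), ("R", True), ("NALLCSNS", False)],
    )
    def test_cterm_rule(self, seq, expected):
        assert cterm_rule(Peptide(seq)) is expected

    def test_cterm_rule_is_positional(self):
        # same composition, different tail
        assert cterm_rule(Peptide("GGGK"))
        assert not cterm_rule(Peptide("KGGGGG"))

    @given(sequences)
    def test_census_sums_to_n(self, seq):
        census = residue_census(Peptide(seq))
        assert sum(census.values()) == len(seq)

    def test_census_example(self):
        assert residue_census(Peptide("CCYSVY")) == {"C": 2, "Y": 2, "S": 1, "V": 1}
        census = residue_census(Peptide("DCHYFL"))
        assert census["C"] == 1 and census["H"] == 1

    def test_class_config_validation(self):
        with pytest.raises(ValueError):
            ResidueClassConfig(hydrophobic_set=frozenset("AK"),
                               basic_set=frozenset("KR"))
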