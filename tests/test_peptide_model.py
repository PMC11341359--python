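"""Peptide representation, edits, masses and molar doses."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from impurisk.fixtures import API_SEQUENCE, HUMAN_CALCITONIN, api_peptide
from impurisk.peptide_model import (
    CANONICAL,
    EditOperation,
    ModifiedPeptide,
    PeptideError,
    Residue,
    SubstitutionTable,
    apply_edit,
    average_mass,
    load_impurity_spec,
    mass_table,
    molar_concentration,
    naturalize,
    percent_identity,
    read_fasta,
    write_fasta,
)

WATER = 18.0153


class TestResidueInvariants:
    def test_rejects_non_canonical_code(self):
        with pytest.raises(PeptideError):
            Residue("B")

    def test_rejects_incompatible_modification(self):
        with pytest.raises(PeptideError):
            Residue("A", "acetyl-K")

    def test_acetyl_only_on_lysine(self):
        assert Residue("K", "acetyl-K").code == "K"


class TestPeptideInvariants:
    def test_disulfide_must_be_cysteine(self):
        with pytest.raises(PeptideError):
            ModifiedPeptide.from_sequence("x", "ACDEF", disulfide_pairs=[(1, 3)])

    def test_disulfide_out_of_range(self):
        with pytest.raises(PeptideError):
            ModifiedPeptide.from_sequence("x", "CC", disulfide_pairs=[(1, 5)])

    def test_nonpositive_abundance_rejected(self):
        with pytest.raises(PeptideError):
            ModifiedPeptide.from_sequence("x", "ACD", relative_abundance_pct=0)


class TestApplyEdit:
    def test_deletion_removes_stated_residue(self, api):
        imp = apply_edit(api, EditOperation("deletion", 21))
        assert imp.sequence == API_SEQUENCE[:20] + API_SEQUENCE[21:]
        # the C-terminal window of the deletion impurity as assayed
        assert "SQELHKLQYPRTNTGSGT" in imp.sequence
        assert imp.name == "DES-THR21_SCT"

    def test_insertion_duplicates_glycine(self, api):
        imp = apply_edit(api, EditOperation("insertion", 28, "G"))
        assert len(imp) == 33
        assert imp.sequence[27:29] == "GG"
        assert imp.sequence == "CSNLSTCVLGKLSQELHKLQTYPRTNTGGSGTP"

    def test_identity_substitution_preserves_sequence(self, api):
        imp = apply_edit(api, EditOperation("substitution", 5, "S"))
        assert imp.sequence == api.sequence

    def test_deletion_insertion_round_trip(self, api):
        deleted = apply_edit(api, EditOperation("deletion", 21))
        restored = apply_edit(deleted, EditOperation("insertion", 21, "T"))
        assert restored.sequence == api.sequence
        assert restored.disulfide_pairs == api.disulfide_pairs

    def test_disulfide_reindexed_across_nterminal_indel(self):
        p = ModifiedPeptide.from_sequence("x", "ACDCEFGHI", disulfide_pairs=[(2, 4)])
        ins = apply_edit(p, EditOperation("insertion", 1, "G"))
        assert ins.disulfide_pairs == ((3, 5),)
        dele = apply_edit(p, EditOperation("deletion", 1))
        assert dele.disulfide_pairs == ((1, 3),)

    def test_deleting_a_bridged_cysteine_drops_the_pair(self):
        p = ModifiedPeptide.from_sequence("x", "ACDCEF", disulfide_pairs=[(2, 4)])
        assert apply_edit(p, EditOperation("deletion", 2)).disulfide_pairs == ()

    def test_position_out_of_range(self, api):
        with pytest.raises(PeptideError):
            apply_edit(api, EditOperation("deletion", 40))

    def test_incompatible_modification(self, api):
        with pytest.raises(PeptideError):
            apply_edit(api, EditOperation("side_chain_mod", 1, "acetyl-K"))  # C1


class TestAverageMass:
    def test_glycine_monopeptide(self):
        g = ModifiedPeptide.from_sequence("g", "G")
        assert average_mass(g) == pytest.approx(75.07, abs=0.01)

    def test_api_mass_matches_independent_calculation(self, api):
        # Biopython's average protein weight as the independent oracle for
        # the unmodified chain; amide and disulfide corrections are additive.
        from Bio.SeqUtils import molecular_weight

        chain = molecular_weight(API_SEQUENCE, seq_type="protein", monoisotopic=False)
        assert average_mass(api) == pytest.approx(chain - 0.9847 - 2.0159, abs=0.1)
        assert average_mass(api) == pytest.approx(3431.9, abs=0.1)

    def test_insertion_mass_additivity(self, api):
        imp = apply_edit(api, EditOperation("insertion", 28, "G"))
        assert average_mass(imp) - average_mass(api) == pytest.approx(
            mass_table()["G"], abs=1e-9
        )

    def test_acetylation_delta(self, api):
        imp = apply_edit(api, EditOperation("side_chain_mod", 18, "acetyl-K"))
        assert average_mass(imp) - average_mass(api) == pytest.approx(42.0367)

    @given(st.text(alphabet=CANONICAL, min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_mass_exceeds_water_for_any_chain(self, seq):
        p = ModifiedPeptide.from_sequence("x", seq)
        assert average_mass(p) > WATER


class TestMolarConcentration:
    @pytest.mark.parametrize(
        "edit,expected",
        [
            (None, 5.8),
            (EditOperation("side_chain_mod", 18, "acetyl-K"), 5.8),
            (EditOperation("substitution", 20, "E"), 5.8),
            (EditOperation("insertion", 28, "G"), 5.7),
            (EditOperation("insertion", 31, "T"), 5.7),
        ],
    )
    def test_case_study_doses(self, api, edit, expected):
        pep = api if edit is None else apply_edit(api, edit)
        assert molar_concentration(20.0, pep) == expected

    def test_zero_concentration_rejected(self, api):
        with pytest.raises(PeptideError):
            molar_concentration(0.0, api)

    def test_linearity(self, api):
        assert molar_concentration(40.0, api) == pytest.approx(
            2 * (20.0 / average_mass(api) * 1000), abs=0.05
        )

    def test_decreasing_in_mass(self, api):
        heavier = apply_edit(api, EditOperation("insertion", 28, "W"))
        assert molar_concentration(20.0, heavier) < molar_concentration(20.0, api)


class TestNaturalize:
    def test_unmodified_returns_itself(self, api):
        out = naturalize(api)
        assert out == [(api.sequence, ())]

    def test_acetyl_lysine_maps_to_glutamine(self):
        p = ModifiedPeptide.from_sequence("x", "AKA", modifications={2: "acetyl-K"})
        out = naturalize(p, SubstitutionTable({"acetyl-K": ("Q",)}))
        assert out == [("AQA", ((2, "acetyl-K", "Q"),))]

    def test_deamidated_glutamine_needs_no_table(self):
        p = ModifiedPeptide.from_sequence("x", "AQA", modifications={2: "deamidated-Q"})
        out = naturalize(p)
        assert out[0][0] == "AEA"

    def test_combination_count_is_product(self):
        table = SubstitutionTable({"acetyl-K": ("Q", "R", "N")})
        p = ModifiedPeptide.from_sequence(
            "x", "KAKA", modifications={1: "acetyl-K", 3: "acetyl-K"}
        )
        assert len(naturalize(p, table)) == 9

    def test_cap_enforced(self):
        table = SubstitutionTable({"acetyl-K": tuple("QRNDEHSTAG")})
        p = ModifiedPeptide.from_sequence(
            "x", "KK", modifications={1: "acetyl-K", 2: "acetyl-K"}
        )
        with pytest.raises(PeptideError):
            naturalize(p, table, cap=50)


class TestPercentIdentity:
    def test_identical(self):
        assert percent_identity("ACDEF", "ACDEF") == 100.0

    def test_salmon_vs_human_calcitonin(self):
        assert percent_identity(API_SEQUENCE, HUMAN_CALCITONIN) == 50.0

    def test_disjoint(self):
        assert percent_identity("AAAA", "CCCC") == 0.0

    def test_length_mismatch_raises(self):
        with pytest.raises(PeptideError):
            percent_identity("AC", "ACD")


class TestIO:
    def test_fasta_round_trip(self, tmp_path, api):
        path = tmp_path / "p.fasta"
        write_fasta([api], path)
        (rec,) = read_fasta(path)
        assert rec.sequence == api.sequence

    def test_impurity_spec_json(self, tmp_path, api):
        path = tmp_path / "imps.json"
        path.write_text(
            '[{"name": "DES-THR21_SCT", '
            '"edits": [{"kind": "deletion", "position": 21}], '
            '"abundance_pct": 1.5}]'
        )
        (imp,) = load_impurity_spec(path, api)
        assert imp.name == "DES-THR21_SCT"
        assert len(imp) == 31
        assert imp.relative_abundance_pct == 1.5
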