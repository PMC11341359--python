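"""Frame enumeration, calibration, hit calling, EpiBars, aggregate score."""

import numpy as np
import pandas as pd
import pytest

from impurisk.epitope_scan import (
    FrameHitTable,
    ScanError,
    ScoringMatrixSet,
    Z_ELEVATED,
    Z_HIT,
    aggregate_score,
    calibrate,
    default_matrices,
    detect_epibars,
    enumerate_frames,
    frame_score,
    read_matrix_tsv,
    scan,
    write_matrix_tsv,
)
from impurisk.peptide_model import ModifiedPeptide
from impurisk.synthetic_data import gen_background_peptides

from conftest import crafted_matrix_for


class TestEnumerateFrames:
    @pytest.mark.parametrize("length,expected", [(9, 1), (10, 2), (32, 24)])
    def test_frame_count(self, length, expected):
        seq = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMN"[:length]
        assert len(enumerate_frames(seq)) == expected

    def test_adjacent_frames_share_eight(self):
        f = enumerate_frames("ACDEFGHIKL")
        assert f[0][1:] == f[1][:8]

    def test_too_short_raises(self):
        with pytest.raises(ScanError):
            enumerate_frames("ACDEFGHI")


class TestCalibration:
    def test_degenerate_background_raises(self):
        m = ScoringMatrixSet({"X": np.zeros((9, 20))})
        with pytest.raises(ScanError):
            calibrate(m, gen_background_peptides(50, 18, seed=3))

    def test_affine_invariance_of_z(self, matrices, held_out_background):
        doubled = ScoringMatrixSet(
            {a: 2.0 * m for a, m in matrices.matrices.items()}
        )
        calibrate(doubled, gen_background_peptides(1200, 18, seed=1))
        seq = held_out_background[0]
        for allele in matrices.alleles:
            np.testing.assert_allclose(
                matrices.z_scores(seq, allele), doubled.z_scores(seq, allele)
            )

    def test_held_out_hit_rate_near_five_percent(self, matrices, held_out_background):
        for allele in matrices.alleles:
            z = np.concatenate(
                [matrices.z_scores(s, allele) for s in held_out_background]
            )
            assert 0.04 <= float((z >= Z_HIT).mean()) <= 0.06


class TestScan:
    def test_planted_ninemer_is_hit_for_crafted_allele(self, matrices):
        target = "LHKLQTYPR"
        crafted = dict(matrices.matrices)
        crafted["crafted"] = crafted_matrix_for(target)
        mset = ScoringMatrixSet(crafted)
        calibrate(mset, gen_background_peptides(1200, 18, seed=1))
        table = scan("AAAA" + target + "AAAA", mset)
        cell = table.scores.query("allele == 'crafted' and ninemer == @target")
        assert bool(cell["hit"].iloc[0])

    def test_hits_subset_of_elevated(self, matrices, held_out_background):
        table = scan(held_out_background[0], matrices)
        assert not (table.scores["hit"] & ~table.scores["elevated"]).any()

    def test_all_frames_and_alleles_scored(self, matrices, api):
        table = scan(api, matrices)
        assert table.n_frames == len(api) - 8
        assert table.n_assessments == (len(api) - 8) * len(matrices.alleles)

    def test_deterministic(self, matrices, api):
        t1, t2 = scan(api, matrices), scan(api, matrices)
        pd.testing.assert_frame_equal(t1.scores, t2.scores)

    def test_modified_peptide_rejected(self, matrices):
        p = ModifiedPeptide.from_sequence(
            "x", "AKAAAAAAAA", modifications={2: "acetyl-K"}
        )
        with pytest.raises(ScanError):
            scan(p, matrices)

    def test_unsupported_letter_rejected(self, matrices):
        with pytest.raises(ScanError):
            scan("ACDEFGHIKX", matrices)


def random_hit_table(rng, n_frames=24, n_alleles=9) -> FrameHitTable:
    rows = []
    for f in range(1, n_frames + 1):
        for a in range(n_alleles):
            z = rng.normal()
            rows.append((f, "A" * 9, f"A{a}", z))
    df = pd.DataFrame(rows, columns=["frame", "ninemer", "allele", "z"])
    df["hit"] = df["z"] >= Z_HIT
    df["elevated"] = df["z"] >= Z_ELEVATED
    return FrameHitTable("rand", df, Z_HIT, Z_ELEVATED)


def brute_force_epibars(table: FrameHitTable, min_alleles=4):
    out = []
    for f in sorted(table.scores["frame"].unique()):
        n = sum(
            1
            for r in table.scores.itertuples()
            if r.frame == f and r.z >= table.z_hit
        )
        if n >= min_alleles:
            out.append(int(f))
    return tuple(out)


class TestEpiBars:
    def test_boundary_four_vs_three_hits(self):
        rows = []
        for f, n_hits in [(1, 4), (2, 3)]:
            for a in range(9):
                z = 2.0 if a < n_hits else 0.0
                rows.append((f, "A" * 9, f"A{a}", z))
        df = pd.DataFrame(rows, columns=["frame", "ninemer", "allele", "z"])
        df["hit"] = df["z"] >= Z_HIT
        df["elevated"] = df["z"] >= Z_ELEVATED
        table = FrameHitTable("x", df, Z_HIT, Z_ELEVATED)
        assert detect_epibars(table) == (1,)

    def test_all_zero_table_has_no_epibars(self):
        table = random_hit_table(np.random.default_rng(0))
        table.scores["z"] = 0.0
        table.scores["hit"] = False
        assert detect_epibars(table) == ()

    def test_agrees_with_brute_force_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            table = random_hit_table(rng, n_frames=12, n_alleles=9)
            assert detect_epibars(table) == brute_force_epibars(table)


class TestScores:
    def test_random_background_scores_near_zero(self, matrices):
        peps = gen_background_peptides(500, 18, seed=9)
        scores = np.array([scan(p, matrices).aggregate for p in peps])
        se = scores.std(ddof=1) / np.sqrt(len(scores))
        assert abs(scores.mean()) <= 2 * se + 1e-9

    def test_no_hits_with_positive_background_expectation_is_negative(self, matrices):
        table = random_hit_table(np.random.default_rng(1))
        table.scores["z"] = -1.0
        table.scores["hit"] = False
        assert matrices.background_expectation > 0
        assert aggregate_score(table, matrices) < 0

    def test_adding_a_hit_cell_increases_score(self, matrices):
        table = random_hit_table(np.random.default_rng(2))
        before = aggregate_score(table, matrices)
        idx = table.scores.index[~table.scores["hit"]][0]
        table.scores.loc[idx, ["z", "hit"]] = [2.5, True]
        assert aggregate_score(table, matrices) > before

    def test_frame_score_equals_brute_force(self):
        table = random_hit_table(np.random.default_rng(3))
        for f in (1, 5, 24):
            manual = sum(
                r.z
                for r in table.scores.itertuples()
                if r.frame == f and r.z >= table.z_elevated
            )
            assert frame_score(table, f) == pytest.approx(manual)

    def test_frame_score_two_alleles_at_two(self):
        rows = [(1, "A" * 9, f"A{a}", 2.0 if a < 2 else 0.0) for a in range(9)]
        df = pd.DataFrame(rows, columns=["frame", "ninemer", "allele", "z"])
        df["hit"] = df["z"] >= Z_HIT
        df["elevated"] = df["z"] >= Z_ELEVATED
        table = FrameHitTable("x", df, Z_HIT, Z_ELEVATED)
        assert frame_score(table, 1) == pytest.approx(4.0)

    def test_frame_out_of_range(self):
        table = random_hit_table(np.random.default_rng(4))
        with pytest.raises(ScanError):
            frame_score(table, 99)


class TestMatrixIO:
    def test_tsv_round_trip_preserves_scores(self, tmp_path, matrices, api):
        write_matrix_tsv(matrices, tmp_path)
        loaded = read_matrix_tsv(tmp_path, matrices.alleles)
        t1, t2 = scan(api, matrices), scan(api, loaded)
        pd.testing.assert_frame_equal(t1.scores, t2.scores)

    def test_missing_matrix_file_reports_path(self, tmp_path):
        with pytest.raises(ScanError, match="not found"):
            read_matrix_tsv(tmp_path, ["DRB1*0101"])
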