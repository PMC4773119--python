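"""Exact and seeded duplex search: hand cases, invariants, oracles."""

import numpy as np
import pytest

import duplexscan as ds
from duplexscan.formats_io import SequenceRecord
from duplexscan.scoring import random_sequence

from conftest import plant_complement


class TestExactHandCases:
    def test_gc_at_block(self, matrix):
        alns = ds.align_duplex_exact(
            SequenceRecord("q", "GGGAAA"), SequenceRecord("t", "TTTCCC"), matrix, 10
        )
        assert len(alns) == 1
        a = alns[0]
        assert a.score == 18
        assert a.lnc_interval == (0, 6)
        assert a.target_interval == (0, 6)
        # antiparallel: first query base pairs the last target base
        assert a.columns[0] == ("G", "C") and a.columns[-1] == ("A", "T")

    def test_perfect_27mer_scores_108(self, matrix):
        t = SequenceRecord("t", "GC" * 13 + "G")  # 27-mer, all G/C
        q = SequenceRecord("q", ds.revcomp(t.seq))
        alns = ds.align_duplex_exact(q, t, matrix, 107)
        assert [a.score for a in alns] == [108]

    def test_unpairable_sequences_give_empty(self, matrix):
        alns = ds.align_duplex_exact(
            SequenceRecord("q", "A" * 40), SequenceRecord("t", "A" * 40), matrix, 1
        )
        assert alns == []

    def test_empty_sequence_rejected(self, matrix):
        from types import SimpleNamespace

        with pytest.raises(ValueError, match="empty"):
            ds.align_duplex_exact(
                SequenceRecord("q", "ACGT"), SimpleNamespace(id="t", seq=""),
                matrix, 1,
            )


class TestInvariants:
    def test_scores_recompute_from_columns(self, matrix):
        rng = np.random.default_rng(21)
        checked = 0
        for k in range(40):
            q = SequenceRecord("q", random_sequence(150, rng, 0.65))
            t = SequenceRecord("t", random_sequence(150, rng, 0.65))
            for a in ds.align_duplex_exact(q, t, matrix, 15):
                assert ds.alignment_score(matrix, a.columns) == a.score
                checked += 1
        assert checked >= 20

    def test_antiparallel_and_interval_consistency(self, matrix):
        rng = np.random.default_rng(22)
        for k in range(20):
            q = SequenceRecord("q", random_sequence(120, rng, 0.6))
            t = SequenceRecord("t", random_sequence(120, rng, 0.6))
            for a in ds.align_duplex_exact(q, t, matrix, 14):
                n_q = sum(1 for qc, _ in a.columns if qc != "-")
                n_t = sum(1 for _, tc in a.columns if tc != "-")
                assert a.lnc_interval[1] - a.lnc_interval[0] == n_q
                assert a.target_interval[1] - a.target_interval[0] == n_t
                # columns read off the sequences: ascending q, descending t
                qi, tj = a.lnc_interval[0], a.target_interval[1] - 1
                for qc, tc in a.columns:
                    if qc != "-":
                        assert q.seq[qi] == qc
                        qi += 1
                    if tc != "-":
                        assert t.seq[tj] == tc
                        tj -= 1

    def test_role_swap_symmetry_of_best_score(self, matrix):
        """Hybridization strength does not depend on which molecule is the
        query; the full greedy set can differ only through tie-breaking."""
        rng = np.random.default_rng(23)
        for k in range(15):
            q = random_sequence(100, rng, 0.6)
            t = random_sequence(100, rng, 0.6)
            assert ds.best_duplex_score(q, t, matrix) == ds.best_duplex_score(
                t, q, matrix
            )

    def test_role_swap_symmetry_of_unique_optimum(self, matrix):
        rng = np.random.default_rng(26)
        lnc, tgt, score, lnc_iv, tgt_iv = plant_complement(rng, 150, 25, 10, guard=8)
        fwd = ds.align_duplex_exact(lnc, tgt, matrix, 100)
        rev = ds.align_duplex_exact(tgt, lnc, matrix, 100)
        assert [(a.score, a.lnc_interval, a.target_interval) for a in fwd] == [
            (score, lnc_iv, tgt_iv)
        ]
        assert [(a.score, a.lnc_interval, a.target_interval) for a in rev] == [
            (score, tgt_iv, lnc_iv)
        ]

    def test_mask_run_splits_alignments_when_crossing_is_unprofitable(self, matrix):
        """An N run whose mismatch cost exceeds what either side can add acts
        as a hard wall: the two flanking complements come back as separate
        duplexes, neither containing a masked base."""
        rng = np.random.default_rng(24)
        for k in range(8):
            left = random_sequence(80, rng, 0.7)
            right = random_sequence(80, rng, 0.7)
            # each side can contribute at most 4*80 = 320 < 50*6 crossing cost
            n_run = "N" * 50
            t = SequenceRecord("t", left + n_run + right)
            q = SequenceRecord("q", ds.revcomp(right) + "TTT" + ds.revcomp(left))
            alns = ds.align_duplex_exact(q, t, matrix, 30)
            assert len(alns) == 2
            for a in alns:
                s, e = a.target_interval
                assert "N" not in t.seq[s:e]

    def test_rerun_is_deterministic(self, matrix):
        rng = np.random.default_rng(25)
        q = SequenceRecord("q", random_sequence(400, rng, 0.6))
        t = SequenceRecord("t", random_sequence(400, rng, 0.6))
        assert ds.align_duplex_exact(q, t, matrix, 20) == ds.align_duplex_exact(
            q, t, matrix, 20
        )


class TestSeeded:
    def test_seed_len_below_four_rejected(self, matrix):
        with pytest.raises(ValueError):
            ds.align_duplex_seeded(
                SequenceRecord("q", "ACGT" * 10), SequenceRecord("t", "ACGT" * 10),
                matrix, 10, seed_len=3,
            )

    def test_planted_duplex_recovered_on_seed_path(self, matrix):
        """Above the exhaustive cutoff the seeded path matches the oracle."""
        rng = np.random.default_rng(31)
        lnc, tgt, score, lnc_iv, tgt_iv = plant_complement(
            rng, flank_len=900, n_gc=30, n_at=10, guard=8
        )
        assert len(lnc.seq) * len(tgt.seq) > ds.duplex_align.DEFAULT_EXHAUSTIVE_CELLS
        seeded = ds.align_duplex_seeded(lnc, tgt, matrix, 107, seed_len=10)
        exact = ds.align_duplex_exact(lnc, tgt, matrix, 107)
        assert len(seeded) == 1
        assert seeded[0].score == score == 4 * 30 + 2 * 10
        assert seeded[0].lnc_interval == lnc_iv
        assert seeded[0].target_interval == tgt_iv
        assert [(a.score, a.lnc_interval, a.target_interval) for a in seeded] == [
            (a.score, a.lnc_interval, a.target_interval) for a in exact
        ]

    def test_random_large_pair_usually_empty_at_calibrated_threshold(self, matrix):
        thr, _ = ds.calibrate_threshold(
            matrix, 1000, 1000, 1.0, {"length": 500}, n_null_pairs=80, seed=41
        )
        rng = np.random.default_rng(42)
        hits = 0
        for k in range(10):
            q = SequenceRecord("q", random_sequence(1000, rng))
            t = SequenceRecord("t", random_sequence(1000, rng))
            hits += bool(ds.align_duplex_seeded(q, t, matrix, thr))
        assert hits <= 3

    def test_seeded_is_deterministic(self, matrix):
        rng = np.random.default_rng(33)
        lnc, tgt, *_ = plant_complement(rng, flank_len=900, n_gc=28, n_at=8, guard=8)
        a = ds.align_duplex_seeded(lnc, tgt, matrix, 100)
        b = ds.align_duplex_seeded(lnc, tgt, matrix, 100)
        assert a == b

    def test_two_planted_duplexes_both_found(self, matrix):
        rng = np.random.default_rng(34)
        seg1 = "".join(rng.choice(list("GC"), size=30))
        seg2 = "".join(rng.choice(list("GC"), size=28))
        pad = "A" * 8
        tgt = SequenceRecord(
            "t",
            random_sequence(600, rng) + pad + seg1 + pad
            + random_sequence(300, rng) + pad + seg2 + pad + random_sequence(600, rng),
        )
        lnc = SequenceRecord(
            "q",
            random_sequence(400, rng) + pad + ds.revcomp(seg2) + pad
            + random_sequence(200, rng) + pad + ds.revcomp(seg1) + pad
            + random_sequence(400, rng),
        )
        hits = ds.align_duplex_seeded(lnc, tgt, matrix, 107)
        assert sorted(a.score for a in hits) == [112, 120]


class TestSearchTranscriptome:
    def test_fixture_pairs_yield_single_planted_hit(self, matrix):
        rng = np.random.default_rng(51)
        lnc, tgt, score, *_ = plant_complement(rng, 200, 30, 10, guard=8)
        lnc2 = SequenceRecord("lnc2", random_sequence(300, rng))
        tgt2 = SequenceRecord("tgt2", random_sequence(300, rng))
        hits = ds.search_transcriptome([lnc, lnc2], [tgt, tgt2], matrix, 107)
        assert [(h.lnc_id, h.target_id, h.score) for h in hits] == [("lnc", "tgt", score)]

    def test_empty_lnc_set_rejected(self, matrix):
        with pytest.raises(ValueError):
            ds.search_transcriptome([], [SequenceRecord("t", "ACGT")], matrix, 10)

    def test_id_collision_rejected(self, matrix):
        rec = SequenceRecord("same", "ACGTACGT")
        with pytest.raises(ValueError, match="collision"):
            ds.search_transcriptome([rec], [rec], matrix, 10)


class TestIndependentOracle:
    def test_best_score_matches_biopython_pairwise_aligner(self, matrix):
        """Cross-check the DP against Bio.Align.PairwiseAligner on the
        transformed (query vs reverse-complement target) problem."""
        from Bio import Align
        from Bio.Align import substitution_matrices

        sub = substitution_matrices.Array(alphabet="ACGTN", dims=2)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
        for a in "ACGTN":
            for b in "ACGTN":
                sub[a, b] = ds.pair_score(matrix, a, comp[b])
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = sub
        aligner.open_gap_score = matrix.gap_open + matrix.gap_extend
        aligner.extend_gap_score = matrix.gap_extend

        rng = np.random.default_rng(61)
        for k in range(25):
            q = random_sequence(150, rng, [0.4, 0.5, 0.65][k % 3])
            t = random_sequence(150, rng, [0.4, 0.5, 0.65][k % 3])
            expected = aligner.score(q, ds.revcomp(t))
            assert ds.best_duplex_score(q, t, matrix) == int(expected)
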