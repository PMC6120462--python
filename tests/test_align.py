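"""Pairwise alignment, significance statistics, position mapping, MSA.

The dynamic programme is checked against two independent oracles: explicit
enumeration of every alignment path (tiny sequences), and Biopython's
PairwiseAligner (longer random sequences).
"""

import itertools
import math

import numpy as np
import pytest
from Bio import Align as bio_align

from iredmine._dp import brute_force_global, brute_force_local
from iredmine.align import (
    PairwiseAlignment,
    ScoringParams,
    global_align,
    local_align,
    map_positions,
    progressive_msa,
    significance,
)
from iredmine.seqio import SequenceRecord


def rec(sid, seq):
    return SequenceRecord(sid, seq)


class TestPairwise:
    def test_self_alignment_is_gapless_diagonal(self, params):
        a = rec("a", "MKV")
        aln = global_align(a, rec("b", "MKV"), params)
        expected = sum(params.score_pair(x, x) for x in "MKV")
        assert aln.raw_score == expected
        assert aln.columns == [(1, 1), (2, 2), (3, 3)]

    def test_sequence_vs_empty_costs_one_gap_open(self, params):
        # a 1 vs 0 alignment is a single gap column costing gap_open
        from iredmine._dp import affine_dp
        S = np.zeros((1, 0))
        best, *_ = affine_dp(S, float(params.gap_open), float(params.gap_extend), False)
        assert best == params.gap_open

    def test_local_dominates_global_on_identical_sequences(self, params):
        a, b = rec("a", "MKVLYW"), rec("b", "MKVLYW")
        assert local_align(a, b, params).raw_score >= global_align(a, b, params).raw_score

    def test_local_of_unrelated_homopolymers_is_empty(self, params):
        aln = local_align(rec("a", "AAAA"), rec("b", "WWWW"), params)
        assert aln.raw_score == 0
        assert aln.columns == []

    @pytest.mark.parametrize("mode", ["global", "local"])
    def test_exhaustive_enumeration_oracle_short_pairs(self, params, mode):
        """DP optimum equals brute-force path enumeration, lengths <= 3."""
        seqs = ["".join(t) for n in range(1, 4) for t in itertools.product("ACDE", repeat=n)]
        for a in seqs[::3]:
            for b in seqs[::3]:
                S = params.pair_scores(a, b)
                if mode == "global":
                    got = global_align(rec("a", a), rec("b", b), params).raw_score
                    want = brute_force_global(S, float(params.gap_open), float(params.gap_extend))
                else:
                    got = local_align(rec("a", a), rec("b", b), params).raw_score
                    want = brute_force_local(S, float(params.gap_open), float(params.gap_extend))
                assert got == want, (a, b, mode)

    def test_against_biopython_aligner_on_random_sequences(self, params):
        aligner = bio_align.PairwiseAligner()
        aligner.substitution_matrix = bio_align.substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
        rng = np.random.default_rng(42)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(15):
            a = "".join(rng.choice(list(aa), size=rng.integers(10, 40)))
            b = "".join(rng.choice(list(aa), size=rng.integers(10, 40)))
            for mode in ("global", "local"):
                aligner.mode = mode
                func = global_align if mode == "global" else local_align
                assert func(rec("a", a), rec("b", b), params).raw_score == aligner.score(a, b)

    def test_score_symmetry_and_rescore_consistency(self, params):
        rng = np.random.default_rng(3)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(10):
            a = "".join(rng.choice(list(aa), size=rng.integers(5, 30)))
            b = "".join(rng.choice(list(aa), size=rng.integers(5, 30)))
            fa = global_align(rec("a", a), rec("b", b), params)
            fb = global_align(rec("b", b), rec("a", a), params)
            assert fa.raw_score == fb.raw_score
            assert fa.rescore(a, b, params) == fa.raw_score
            la = local_align(rec("a", a), rec("b", b), params)
            assert la.rescore(a, b, params) == la.raw_score

    def test_unknown_letter_rejected(self, params):
        with pytest.raises(ValueError, match="substitution matrix"):
            params.encode("MK1")


class TestSignificance:
    def test_zero_bit_score_gives_E_equal_mn(self, params):
        raw_at_bit0 = math.log(params.karlin_K) / params.karlin_lambda
        bit, e = significance(raw_at_bit0, 300, 1000, params)
        assert abs(bit) < 1e-12
        assert e == pytest.approx(300 * 1000)

    def test_E_linear_in_database_length(self, params):
        _, e1 = significance(100, 250, 10_000, params)
        _, e2 = significance(100, 250, 20_000, params)
        assert e2 == pytest.approx(2 * e1)

    def test_closed_form_evaluation(self, params):
        bit, e = significance(500, 300, 10**6, params)
        expected_bit = (0.267 * 500 - math.log(0.041)) / math.log(2)
        assert bit == pytest.approx(expected_bit)
        assert e == pytest.approx(300 * 10**6 * 2 ** (-expected_bit))
        # E strictly decreasing in the raw score
        assert significance(501, 300, 10**6, params)[1] < e

    def test_nonpositive_lengths_rejected(self, params):
        with pytest.raises(ValueError):
            significance(10, 0, 100, params)


class TestPositionMap:
    def test_identity_on_ungapped_self_alignment(self, params):
        a = rec("ref", "MKVLYW")
        aln = global_align(a, rec("cand", "MKVLYW"), params)
        pm = map_positions(aln, "ref", [1, 3, 6], len(a))
        assert pm.mapping == {1: 1, 3: 3, 6: 6}

    def test_candidate_gap_shifts_downstream_positions(self, params):
        aln = global_align(rec("ref", "MKVL"), rec("cand", "MVL"), params)
        pm = map_positions(aln, "ref", [1, 2, 3, 4], 4)
        assert pm.mapping[3] == 2  # V lands left of the K deletion
        assert pm.mapping[4] == 3
        assert pm.mapping[2] is None  # K sits opposite the candidate gap

    def test_position_outside_reference_is_an_error(self, params):
        aln = global_align(rec("ref", "MKVL"), rec("cand", "MKVL"), params)
        with pytest.raises(ValueError, match="outside reference"):
            map_positions(aln, "ref", [5], 4)

    def test_monotone_and_injective_on_random_alignments(self, params):
        rng = np.random.default_rng(8)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(10):
            a = "".join(rng.choice(list(aa), size=25))
            b = "".join(rng.choice(list(aa), size=rng.integers(15, 35)))
            aln = global_align(rec("ref", a), rec("cand", b), params)
            pm = map_positions(aln, "ref", range(1, 26), 25)
            mapped = [v for v in pm.mapping.values() if v is not None]
            assert mapped == sorted(mapped)
            assert len(mapped) == len(set(mapped))


class TestProgressiveMSA:
    def test_identical_sequences_align_gap_free(self, params):
        recs = [rec(f"s{i}", "MKVLYWMKVL") for i in range(4)]
        msa = progressive_msa(recs, params)
        assert msa.n_columns == 10
        assert all(row == "MKVLYWMKVL" for row in msa.rows)

    def test_two_sequences_reduce_to_pairwise(self, params):
        a, b = rec("a", "MKVLY"), rec("b", "MVLY")
        msa = progressive_msa([a, b], params)
        aln = global_align(a, b, params)
        from iredmine.align import _rows_from_pairwise
        assert tuple(msa.rows) == _rows_from_pairwise(aln, a.residues, b.residues)

    def test_degap_identity_and_planted_columns(self, params, positives_only):
        fam = positives_only
        msa = progressive_msa(fam.records + [fam.reference], params)
        for r in fam.records:
            assert msa.degapped(r.id) == r.residues
        # every planted key residue lands in the reference's key column
        for pos in fam.config.key_positions:
            col = msa.column_of("REF", pos)
            for r in fam.records:
                assert msa.row(r.id)[col] == fam.truth[r.id].key_residues[pos]

    def test_requires_two_sequences(self, params):
        with pytest.raises(ValueError):
            progressive_msa([rec("a", "MK")], params)
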