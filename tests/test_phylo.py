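"""Distances, neighbour joining, newick round trips and branch typing."""

import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix as SkbioDM
from skbio.tree import nj as skbio_nj

from iredmine.align import MultipleAlignment
from iredmine.phylo import (
    DistanceMatrix,
    assign_branch_types,
    neighbor_joining,
    pairwise_distance,
    parse_newick,
    rf_distance,
    to_newick,
)
from iredmine.simulate import additive_matrix_from_tree, random_tree


class TestPairwiseDistance:
    def test_identical_rows_give_zero_matrix(self):
        msa = MultipleAlignment(["a", "b", "c"], ["MKVL"] * 3)
        assert np.all(pairwise_distance(msa, "p").data == 0)
        assert np.all(pairwise_distance(msa, "poisson").data == 0)

    def test_p_distance_is_mismatch_fraction(self):
        row_a = "A" * 100
        row_b = "C" * 10 + "A" * 90
        msa = MultipleAlignment(["a", "b"], [row_a, row_b])
        assert pairwise_distance(msa, "p")[("a", "b")] == pytest.approx(0.10)

    def test_poisson_correction(self):
        row_a = "A" * 100
        row_b = "C" * 10 + "A" * 90
        msa = MultipleAlignment(["a", "b"], [row_a, row_b])
        d = pairwise_distance(msa, "poisson")[("a", "b")]
        assert d == pytest.approx(-np.log(0.9), abs=1e-10)

    def test_gapped_columns_excluded_pairwise(self):
        msa = MultipleAlignment(["a", "b"], ["AC-G", "ACCG"])
        assert pairwise_distance(msa, "p")[("a", "b")] == 0.0

    def test_disjoint_rows_error(self):
        msa = MultipleAlignment(["a", "b"], ["AC--", "--AC"])
        with pytest.raises(ValueError, match="no ungapped column"):
            pairwise_distance(msa)

    def test_saturated_pair_rejected_under_poisson(self):
        msa = MultipleAlignment(["a", "b"], ["AAAA", "CCCC"])
        with pytest.raises(ValueError, match="[Ss]aturated"):
            pairwise_distance(msa, "poisson")


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree ((A:0.1,B:0.2):0.15,C:0.05,D:0.3)
        ids = ["A", "B", "C", "D"]
        d = {
            ("A", "B"): 0.3, ("A", "C"): 0.3, ("A", "D"): 0.55,
            ("B", "C"): 0.4, ("B", "D"): 0.65, ("C", "D"): 0.35,
        }
        mat = np.zeros((4, 4))
        for (x, y), v in d.items():
            i, j = ids.index(x), ids.index(y)
            mat[i, j] = mat[j, i] = v
        tree = neighbor_joining(DistanceMatrix(ids, mat))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 0.1, "B": 0.2, "C": 0.05, "D": 0.3})
        internal = [n.length for n in tree.non_tips()]
        assert internal == pytest.approx([0.15])
        induced = additive_matrix_from_tree(tree)
        for (x, y), v in d.items():
            assert induced[(x, y)] == pytest.approx(v, abs=1e-12)

    def test_star_matrix_gives_zero_internal_branch(self):
        mat = np.full((4, 4), 0.2)
        np.fill_diagonal(mat, 0.0)
        tree = neighbor_joining(DistanceMatrix(list("ABCD"), mat))
        internal = [n.length for n in tree.non_tips()]
        assert internal == pytest.approx([0.0], abs=1e-12)

    def test_random_additive_matrices_recovered(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            true = random_tree(int(rng.integers(4, 13)), rng)
            D = additive_matrix_from_tree(true)
            est = neighbor_joining(D)
            assert rf_distance(true, est) == 0
            induced = additive_matrix_from_tree(est)
            assert induced.ids == D.ids
            assert np.abs(induced.data - D.data).max() < 1e-9

    def test_agrees_with_skbio_topology(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            true = random_tree(8, rng)
            D = additive_matrix_from_tree(true)
            mine = neighbor_joining(D)
            other = parse_newick(str(skbio_nj(SkbioDM(D.data, D.ids))))
            assert rf_distance(mine, other) == 0

    def test_four_point_condition_on_induced_distances(self):
        rng = np.random.default_rng(9)
        true = random_tree(7, rng)
        D = additive_matrix_from_tree(neighbor_joining(additive_matrix_from_tree(true)))
        for q in itertools.combinations(D.ids, 4):
            sums = sorted(
                D[(q[a], q[b])] + D[(q[c], q[d])]
                for (a, b), (c, d) in [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]
            )
            assert sums[2] - sums[1] < 1e-9  # two largest sums are equal

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_negative_estimates_clamped_with_warning(self):
        mat = np.array(
            [[0, 0.01, 0.5, 0.5],
             [0.01, 0, 0.2, 0.2],
             [0.5, 0.2, 0, 0.3],
             [0.5, 0.2, 0.3, 0]]
        )
        with pytest.warns(UserWarning, match="clamped"):
            tree = neighbor_joining(DistanceMatrix(list("ABCD"), mat))
        assert all((t.length or 0) >= 0 for t in tree.traverse())


class TestNewick:
    def test_three_taxon_star_form(self):
        mat = np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]])
        tree = neighbor_joining(DistanceMatrix(list("ABC"), mat))
        nwk = to_newick(tree)
        assert nwk.startswith("(A:") and nwk.endswith(";")
        assert nwk.count(",") == 2

    def test_round_trip_preserves_topology_and_lengths(self):
        rng = np.random.default_rng(21)
        tree = neighbor_joining(additive_matrix_from_tree(random_tree(9, rng)))
        back = parse_newick(to_newick(tree))
        assert rf_distance(tree, back) == 0
        d1 = additive_matrix_from_tree(tree)
        d2 = additive_matrix_from_tree(back)
        assert np.abs(d1.data - d2.data).max() < 1e-10

    def test_serialisation_is_deterministic(self):
        rng1 = np.random.default_rng(33)
        rng2 = np.random.default_rng(33)
        t1 = neighbor_joining(additive_matrix_from_tree(random_tree(6, rng1)))
        t2 = neighbor_joining(additive_matrix_from_tree(random_tree(6, rng2)))
        assert to_newick(t1) == to_newick(t2)


class TestBranchTypes:
    def test_planted_clades_are_monophyletic(self, positives_only):
        fam = positives_only
        tree = neighbor_joining(additive_matrix_from_tree(fam.tree))
        calls = {r.id: fam.truth[r.id].donor_type for r in fam.records}
        _, summary = assign_branch_types(tree, calls)
        assert summary.monophyletic == {"D-type": True, "Y-type": True}
        assert summary.counts["D-type"] + summary.counts["Y-type"] == len(fam.records)

    def test_single_type_is_trivially_monophyletic(self):
        rng = np.random.default_rng(2)
        tree = random_tree(5, rng)
        calls = {t.name: "D-type" for t in tree.tips()}
        _, summary = assign_branch_types(tree, calls)
        assert summary.monophyletic == {"D-type": True}

    def test_misplaced_leaf_reports_paraphyly_not_error(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,(D:1,E:1):1):1);")
        # E sits inside the otherwise Y-type clade {C, D}
        calls = {"A": "D-type", "B": "D-type", "C": "Y-type", "D": "Y-type", "E": "D-type"}
        _, summary = assign_branch_types(tree, calls)
        assert summary.monophyletic == {"D-type": False, "Y-type": False}

    def test_missing_call_is_an_error(self):
        rng = np.random.default_rng(2)
        tree = random_tree(4, rng)
        with pytest.raises(ValueError, match="missing donor call"):
            assign_branch_types(tree, {})
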