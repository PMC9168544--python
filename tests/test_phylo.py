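"""Distance matrices, NJ, rooting, bootstrap and the HGT topology test."""

import itertools
import math

import dendropy
import numpy as np
import pytest
from oracles import affine_score, enumerate_global_alignments

from triadminer import (
    DistanceMatrix,
    bootstrap_support,
    distance_matrix,
    gen_hgt_scenario,
    global_align,
    hgt_consistency,
    is_monophyletic,
    midpoint_root,
    neighbor_joining,
)
from triadminer.phylo import leaf_labels, to_newick


def _tree(newick: str, rooted=True) -> dendropy.Tree:
    t = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    t.is_rooted = rooted
    return t


def _leaf_dist(tree: dendropy.Tree, a: str, b: str) -> float:
    pdm = tree.phylogenetic_distance_matrix()
    ta = tree.taxon_namespace.get_taxon(a)
    tb = tree.taxon_namespace.get_taxon(b)
    return pdm.distance(ta, tb)


class TestGlobalAlign:
    def test_identity_case(self):
        (_, _), ident = global_align("HEAG", "HEAG")
        assert ident == 100.0

    def test_score_symmetry(self, rng):
        from Bio.Align import substitution_matrices

        for _ in range(5):
            a = "".join(rng.choice(list("ACDEFGHIK"), size=6))
            b = "".join(rng.choice(list("ACDEFGHIK"), size=5))
            (aa1, ab1), i1 = global_align(a, b)
            (aa2, ab2), i2 = global_align(b, a)
            assert i1 == pytest.approx(i2)

    def test_brute_force_optimal_score(self, rng):
        """Aligner score equals exhaustive enumeration over all alignments."""
        from Bio import Align
        from Bio.Align import substitution_matrices

        sub = substitution_matrices.load("BLOSUM62")
        for _ in range(6):
            a = "".join(rng.choice(list("ACDEFG"), size=int(rng.integers(2, 5))))
            b = "".join(rng.choice(list("ACDEFG"), size=int(rng.integers(2, 5))))
            best = max(
                affine_score(cols, sub, gap_open=10.0, gap_extend=0.5)
                for cols in enumerate_global_alignments(a, b)
            )
            aligner = Align.PairwiseAligner()
            aligner.mode = "global"
            aligner.substitution_matrix = sub
            aligner.open_gap_score = -10.0
            aligner.extend_gap_score = -0.5
            assert aligner.score(a, b) == pytest.approx(best)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            global_align("", "AA")


class TestDistanceMatrix:
    def test_identical_zero(self):
        dm = distance_matrix([("a", "MKVL"), ("b", "MKVL"), ("c", "MKVL")])
        assert dm.d.max() == 0

    def test_hand_computed_poisson(self):
        dm = distance_matrix([("a", "AAAA"), ("b", "AAAC")], correction="poisson")
        assert dm.d[0, 1] == pytest.approx(-math.log(0.75), abs=1e-10)
        dm_p = distance_matrix([("a", "AAAA"), ("b", "AAAC")])
        assert dm_p.d[0, 1] == pytest.approx(0.25)

    def test_pairwise_deletion(self):
        dm = distance_matrix([("a", "A-AA"), ("b", "ACAC")])
        assert dm.d[0, 1] == pytest.approx(1 / 3)

    def test_no_shared_columns_errors(self):
        with pytest.raises(ValueError, match="shared"):
            distance_matrix([("a", "A--"), ("b", "-CC")])

    def test_symmetry_and_diagonal(self, rng):
        msa = [
            (f"s{i}", "".join(rng.choice(list("ACDE"), size=30))) for i in range(6)
        ]
        dm = distance_matrix(msa)
        np.testing.assert_allclose(dm.d, dm.d.T)
        np.testing.assert_allclose(np.diag(dm.d), 0)


def _additive_matrix():
    # tree ((A:2,B:3):1,C:4,D:5) with internal edge 1 between {A,B} and {C,D}
    labels = ("A", "B", "C", "D")
    d = np.array(
        [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], dtype=float
    )
    return DistanceMatrix(labels, d)


class TestNeighborJoining:
    def test_additive_recovery(self):
        """NJ reproduces leaf-to-leaf path lengths of an additive matrix."""
        dm = _additive_matrix()
        tree = neighbor_joining(dm)
        for i, a in enumerate(dm.labels):
            for j, b in enumerate(dm.labels):
                if i < j:
                    assert _leaf_dist(tree, a, b) == pytest.approx(dm.d[i, j], abs=1e-9)
        # {A,B} must be a cherry
        nwk = to_newick(tree)
        assert "(A:" in nwk or "A:2.000000,B:3.000000" in nwk.replace("(", "")

    def test_three_leaf_closed_form(self):
        labels = ("x", "y", "z")
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        # three-point formulas: bx=1, by=2, bz=3
        for leaf, expect in (("x", 1.0), ("y", 2.0), ("z", 3.0)):
            node = tree.find_node_with_taxon_label(leaf)
            assert node.edge.length == pytest.approx(expect)

    def test_row_permutation_invariance(self):
        dm = _additive_matrix()
        perm = [2, 0, 3, 1]
        dm2 = DistanceMatrix(
            tuple(dm.labels[i] for i in perm), dm.d[np.ix_(perm, perm)]
        )
        t1, t2 = neighbor_joining(dm), neighbor_joining(dm2)
        for a, b in itertools.combinations(dm.labels, 2):
            assert _leaf_dist(t1, a, b) == pytest.approx(_leaf_dist(t2, a, b))

    def test_too_few_leaves(self):
        with pytest.raises(ValueError):
            neighbor_joining(
                DistanceMatrix(("a", "b"), np.array([[0, 1], [1, 0]], dtype=float))
            )

    def test_against_skbio_on_random_additive(self, rng):
        """Independent oracle: scikit-bio's NJ on random additive matrices."""
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        for _ in range(5):
            # random additive matrix from a random tree on 6 leaves
            tree, _ = gen_hgt_scenario(
                n_bacterial_clades=2, leaves_per_clade=2, n_plants=2,
                branch_scale=1.0, seed=int(rng.integers(1000)),
            )
            pdm = tree.phylogenetic_distance_matrix()
            taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
            labels = tuple(t.label for t in taxa)
            n = len(labels)
            d = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    d[i, j] = d[j, i] = pdm.distance(taxa[i], taxa[j])
            ours = neighbor_joining(DistanceMatrix(labels, d))
            theirs = sk_nj(SkDM(d, ids=labels))
            for a, b in itertools.combinations(labels, 2):
                assert _leaf_dist(ours, a, b) == pytest.approx(
                    theirs.find(a).distance(theirs.find(b)), abs=1e-6
                )


class TestMidpointRoot:
    def test_two_branch_tree(self):
        t = midpoint_root(_tree("(A:1,B:3);", rooted=False))
        root = t.seed_node
        depths = sorted(
            sum(e.length for e in lf.ancestor_iter_through_edges())
            if False else lf.distance_from_root()
            for lf in t.leaf_node_iter()
        )
        assert depths == pytest.approx([2.0, 2.0])

    def test_long_pendant_branch(self):
        # caterpillar with one very long pendant: root must lie on it
        t = midpoint_root(_tree("((A:1,B:1):1,(C:1,D:20):1);", rooted=False))
        d_leaf = t.find_node_with_taxon_label("D")
        # D's path to root shorter than its pendant branch => root on D's edge
        assert d_leaf.distance_from_root() < 20
        # longest path D..A/B = 20+1+1+1 = 23 -> root 11.5 from D
        assert d_leaf.distance_from_root() == pytest.approx(11.5)

    def test_balanced_tree_equal_depths(self):
        t = midpoint_root(_tree("((A:1,B:1):2,(C:1,D:1):2);", rooted=False))
        depths = [lf.distance_from_root() for lf in t.leaf_node_iter()]
        assert max(depths) == pytest.approx(3.0)
        assert sorted(depths)[-2:] == pytest.approx([3.0, 3.0])

    def test_path_lengths_preserved(self, rng):
        tree, _ = gen_hgt_scenario(seed=11)
        rooted = midpoint_root(tree)
        for a, b in [("p0", "p1"), ("b0x0", "b2x1"), ("p0", "b1x0")]:
            assert _leaf_dist(rooted, a, b) == pytest.approx(
                _leaf_dist(tree, a, b), abs=1e-9
            )


class TestMonophyly:
    def test_simple_cases(self):
        t = _tree("((p1,p2),(b1,b2));")
        assert is_monophyletic(t, {"p1", "p2"})
        t2 = _tree("((p1,b1),(p2,b2));")
        assert not is_monophyletic(t2, {"p1", "p2"})

    def test_unknown_taxa_error(self):
        with pytest.raises(ValueError):
            is_monophyletic(_tree("((a,b),c);"), {"a", "zzz"})

    def test_exhaustive_leaf_set_enumeration(self, rng):
        """On random 8-leaf trees, equals direct enumeration of clade leaf sets."""
        for seed in range(5):
            tree, _ = gen_hgt_scenario(
                n_bacterial_clades=2, leaves_per_clade=3, n_plants=2, seed=seed
            )
            clades = set()
            for node in tree.preorder_node_iter():
                clades.add(frozenset(l.taxon.label for l in node.leaf_iter()))
            leaves = sorted(leaf_labels(tree))
            for _ in range(30):
                k = int(rng.integers(1, len(leaves)))
                query = frozenset(rng.choice(leaves, size=k, replace=False))
                assert is_monophyletic(tree, query) == (query in clades)


class TestHgtConsistency:
    def test_planted_scenario(self):
        tree, labels = gen_hgt_scenario(seed=5)
        res = hgt_consistency(tree, labels)
        assert res.monophyletic and res.nesting

    def test_two_origin_topology(self):
        t = _tree("(((p1,b1):1,(p2,b2):1):1,b3:1);")
        labels = {"p1": "plant", "p2": "plant", "b1": "bacteria",
                  "b2": "bacteria", "b3": "bacteria"}
        res = hgt_consistency(t, labels)
        assert not res.monophyletic

    def test_sister_to_all_bacteria_not_nested(self):
        t = _tree("((p1:1,p2:1):1,((b1:1,b2:1):1,b3:2):1);")
        labels = {"p1": "plant", "p2": "plant", "b1": "bacteria",
                  "b2": "bacteria", "b3": "bacteria"}
        res = hgt_consistency(t, labels)
        assert res.monophyletic and not res.nesting


class TestBootstrap:
    def _block_msa(self):
        # zero-homoplasy block structure: {a,b} vs {c,d} differ in a clean block
        return [
            ("a", "AAAAAAAACCCCCCCC"),
            ("b", "AAAAAAAACCCCCCCC"),
            ("c", "AAAAAAAAGGGGGGGG"),
            ("d", "WWWWWWWWGGGGGGGG"),
        ]

    def test_focal_split_full_support(self):
        support = bootstrap_support(self._block_msa(), n_replicates=50, seed=1)
        assert support[frozenset({"c", "d"})] == 1.0

    def test_same_seed_identical(self):
        msa = self._block_msa()
        s1 = bootstrap_support(msa, n_replicates=30, seed=9)
        s2 = bootstrap_support(msa, n_replicates=30, seed=9)
        assert s1 == s2

    def test_single_replicate_binary(self):
        support = bootstrap_support(self._block_msa(), n_replicates=1, seed=4)
        assert set(support.values()) <= {0.0, 1.0}

    def test_bounds_and_trivial_splits(self):
        msa = self._block_msa()
        support = bootstrap_support(msa, n_replicates=20, seed=2)
        assert all(0.0 <= v <= 1.0 for v in support.values())
        assert support[frozenset({"a", "b", "c", "d"})] == 1.0

    def test_replicate_count_validated(self):
        with pytest.raises(ValueError):
            bootstrap_support(self._block_msa(), n_replicates=0, seed=1)
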