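"""Neighbor joining, bootstrap support, rooting, and long-branch flags."""
import numpy as np
import pytest

from deorphan import (
    AlignmentMatrix, DistanceMatrix, bootstrap_support, flag_long_branches,
    msa_distances, neighbor_joining, root_with_outgroup, unroot,
)
from deorphan.tree import PhyloTree
from oracles import additive_matrix, best_topology_by_least_squares, random_additive_tree


def four_taxon_matrix():
    ids = list("ABCD")
    d = np.array([
        [0, 3, 5, 6],
        [3, 0, 6, 7],
        [5, 6, 0, 7],
        [6, 7, 7, 0],
    ], dtype=float)
    return DistanceMatrix(ids, d)


class TestNeighborJoining:
    def test_worked_four_taxon_example(self):
        """Additive matrix from ((A:1,B:2):1,(C:3,D:4)) gives the AB|CD split
        with branch lengths (1, 2, 3, 4, 1)."""
        tree = neighbor_joining(four_taxon_matrix())
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        lengths = {leaf.name: leaf.length for leaf in tree.leaves()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
        internal = [n for n in tree.internal_nodes() if n is not tree.root]
        assert len(internal) == 1 and internal[0].length == pytest.approx(1.0)

    def test_three_taxa_three_point_formulas(self):
        D = DistanceMatrix(list("ABC"), np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float))
        tree = neighbor_joining(D)
        lengths = {leaf.name: leaf.length for leaf in tree.leaves()}
        assert lengths["A"] == pytest.approx((2 + 3 - 5) / 2)
        assert lengths["B"] == pytest.approx((2 + 5 - 3) / 2)
        assert lengths["C"] == pytest.approx((3 + 5 - 2) / 2)

    def test_matches_least_squares_oracle_small(self):
        rng = np.random.default_rng(5)
        for n in (4, 5):
            for _ in range(5):
                true = random_additive_tree(rng, n)
                D = additive_matrix(true)
                nj = neighbor_joining(D)
                ls_bips, sse = best_topology_by_least_squares(D.ids, D)
                assert sse == pytest.approx(0.0, abs=1e-12)
                assert nj.bipartitions() == ls_bips == true.bipartitions()

    def test_recovers_additive_topologies(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            true = random_additive_tree(rng, n)
            nj = neighbor_joining(additive_matrix(true))
            assert nj.bipartitions() == true.bipartitions()
            # unrooted, fully resolved: n leaves, n-3 internal edges, 2n-3 branches
            branches = [x for x in nj.preorder() if x.parent is not None]
            assert len(nj.leaves()) == n
            assert len(branches) == 2 * n - 3

    def test_branch_lengths_recovered_on_additive_input(self):
        rng = np.random.default_rng(7)
        true = random_additive_tree(rng, 6)
        nj = neighbor_joining(additive_matrix(true))
        for a, b in (("t1", "t2"), ("t3", "t5"), ("t2", "t6")):
            assert nj.path_length(a, b) == pytest.approx(true.path_length(a, b))

    def test_deterministic(self):
        a = neighbor_joining(four_taxon_matrix()).to_newick()
        b = neighbor_joining(four_taxon_matrix()).to_newick()
        assert a == b

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]], float)))

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(list("ABC"), np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], float))


def congruent_msa(columns=50):
    return AlignmentMatrix(
        list("ABCD"), ["A" * columns, "A" * columns, "T" * columns, "T" * columns]
    )


class TestBootstrap:
    def test_perfectly_congruent_msa_gives_full_support(self):
        tree = bootstrap_support(congruent_msa(), n_reps=100, seed=0, correction="none")
        support = tree.support_map()
        assert support == {frozenset({"C", "D"}): 100}

    def test_single_replicate_supports_are_zero_or_hundred(self, small_bundle):
        tree = bootstrap_support(small_bundle.msa, n_reps=1, seed=4)
        values = [v for v in tree.support_map().values() if v is not None]
        assert values and set(values) <= {0, 100}

    def test_same_seed_is_bit_reproducible(self, small_bundle):
        t1 = bootstrap_support(small_bundle.msa, n_reps=20, seed=9)
        t2 = bootstrap_support(small_bundle.msa, n_reps=20, seed=9)
        assert t1.to_newick() == t2.to_newick()

    def test_supports_in_range_and_cover_every_internal_edge(self, small_bundle):
        tree = bootstrap_support(small_bundle.msa, n_reps=20, seed=2)
        support = tree.support_map()
        n = len(tree.leaf_names())
        assert len(support) == n - 3  # unrooted fully resolved
        assert all(v is not None and 0 <= v <= 100 for v in support.values())

    def test_invalid_rep_count_rejected(self, small_bundle):
        with pytest.raises(ValueError):
            bootstrap_support(small_bundle.msa, n_reps=0)


class TestRooting:
    def test_four_taxon_root_on_outgroup(self):
        tree = neighbor_joining(four_taxon_matrix())
        rooted = root_with_outgroup(tree, "D")
        kids = {frozenset([l.name for l in PhyloTree(c, rooted=True).leaves()])
                if not c.is_leaf else frozenset([c.name])
                for c in rooted.root.children}
        assert kids == {frozenset({"D"}), frozenset({"A", "B", "C"})}

    def test_path_lengths_preserved(self, small_bundle):
        tree = bootstrap_support(small_bundle.msa, n_reps=5, seed=1)
        rooted = root_with_outgroup(tree, "MCU_HUMAN")
        names = tree.leaf_names()
        for a, b in zip(names, names[1:]):
            assert rooted.path_length(a, b) == pytest.approx(
                tree.path_length(a, b), abs=1e-9
            )

    def test_bipartitions_and_supports_preserved(self, small_bundle):
        tree = bootstrap_support(small_bundle.msa, n_reps=20, seed=1)
        rooted = root_with_outgroup(tree, "MCU_HUMAN")
        assert rooted.rooted
        assert rooted.support_map() == tree.support_map()
        assert unroot(rooted).bipartitions() == tree.bipartitions()

    def test_missing_outgroup_rejected(self):
        tree = neighbor_joining(four_taxon_matrix())
        with pytest.raises(KeyError):
            root_with_outgroup(tree, "NOPE")


class TestLongBranches:
    def make_tree(self, lengths):
        newick = "(" + ",".join(f"t{i}:{x}" for i, x in enumerate(lengths)) + ");"
        return PhyloTree.from_newick(newick, rooted=False)

    def test_equal_branches_give_empty(self):
        assert flag_long_branches(self.make_tree([1, 1, 1, 1])) == []

    def test_outlier_flagged(self):
        assert flag_long_branches(self.make_tree([1, 1, 1, 10]), k=3) == ["t3"]

    def test_monotone_in_k(self):
        tree = self.make_tree([1, 1, 1, 10])
        assert flag_long_branches(tree, k=1e9) == []

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            flag_long_branches(self.make_tree([1, 1, 1]), k=0)
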