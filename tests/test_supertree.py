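import numpy as np
import pytest

from taxograsp.phylo import PhyloTree
from taxograsp.supertree import (build_supertree, spr_distance, spr_neighbors)

from oracles import SprSpace, all_rooted_topologies, random_topology


@pytest.fixture(scope="module")
def space5():
    return SprSpace(list("ABCDE"))


class TestSprDistance:
    def test_identical_trees(self):
        t = PhyloTree((("A", "B"), ("C", "D")))
        res = spr_distance(t, t)
        assert res.k == 0
        assert res.components == (frozenset("ABCD"),)

    def test_single_move_pairs_on_five_leaves(self, space5, rng):
        for _ in range(10):
            t = space5.tops[rng.integers(len(space5.tops))]
            nbs = spr_neighbors(t)
            nb = nbs[rng.integers(len(nbs))]
            assert spr_distance(t, nb).k == 1

    def test_matches_bfs_oracle_on_five_leaves(self, space5, rng):
        for _ in range(30):
            a = space5.tops[rng.integers(len(space5.tops))]
            b = space5.tops[rng.integers(len(space5.tops))]
            assert spr_distance(a, b).k == space5.bfs_distance(a, b)

    def test_symmetry(self, rng):
        labels = list("ABCDEF")
        for _ in range(15):
            a = random_topology(rng, labels)
            b = random_topology(rng, labels)
            assert spr_distance(a, b).k == spr_distance(b, a).k

    def test_forest_partitions_leaves(self, rng):
        labels = list("ABCDEF")
        for _ in range(10):
            a = random_topology(rng, labels)
            b = random_topology(rng, labels)
            res = spr_distance(a, b)
            union = frozenset().union(*res.components)
            assert union == a.leaves
            assert sum(len(c) for c in res.components) == len(a.leaves)

    def test_zero_iff_identical(self, rng):
        labels = list("ABCDE")
        for _ in range(20):
            a = random_topology(rng, labels)
            b = random_topology(rng, labels)
            assert (spr_distance(a, b).k == 0) == (a == b)

    def test_leaf_set_mismatch_lists_difference(self):
        a = PhyloTree(("A", "B"))
        b = PhyloTree(("A", "C"))
        with pytest.raises(ValueError, match="'B'.*'C'|'C'.*'B'"):
            spr_distance(a, b)

    def test_k_max_exceeded_returns_flagged_upper_bound(self, rng):
        labels = [f"l{i}" for i in range(8)]
        a = random_topology(rng, labels)
        b = random_topology(rng, labels)
        exact = spr_distance(a, b)
        if exact.k >= 2:
            capped = spr_distance(a, b, k_max=exact.k - 1)
            assert not capped.exact
            assert capped.k >= exact.k


class TestSprNeighbors:
    def test_neighbors_exclude_self_and_are_unique(self, rng):
        t = random_topology(rng, list("ABCDE"))
        nbs = spr_neighbors(t)
        assert t not in nbs
        assert len(nbs) == len(set(nbs))

    def test_neighborhood_matches_oracle(self, rng):
        from oracles import spr_neighbors_oracle
        for _ in range(5):
            t = random_topology(rng, list("ABCDE"))
            assert set(spr_neighbors(t)) == spr_neighbors_oracle(t)


class TestBuildSupertree:
    def test_copies_of_one_tree(self):
        t = PhyloTree((("A", "B"), ("C", "D")))
        res = build_supertree([t, t, t])
        assert res.tree == t
        assert res.total_spr == 0

    def test_two_trees_one_move_apart(self, space5, rng):
        for _ in range(5):
            t = space5.tops[rng.integers(len(space5.tops))]
            nb = spr_neighbors(t)[0]
            res = build_supertree([t, nb])
            assert res.total_spr == 1
            assert res.tree in (t, nb)

    def test_majority_wins(self, rng):
        t = random_topology(rng, list("ABCDE"))
        t2 = spr_neighbors(t)[3]
        res = build_supertree([t, t, t2])
        assert res.tree == t
        assert res.total_spr == spr_distance(t, t2).k

    def test_never_worse_than_best_input(self, rng):
        labels = list("ABCDE")
        for _ in range(5):
            trees = [random_topology(rng, labels) for _ in range(4)]
            res = build_supertree(trees)
            best_input = min(
                sum(spr_distance(t, u).k for u in trees) for t in trees
            )
            assert res.total_spr <= best_input

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_supertree([])

    def test_mismatched_leaves_rejected(self):
        with pytest.raises(ValueError, match="disagree"):
            build_supertree([PhyloTree(("A", "B")), PhyloTree(("A", "C"))])

    def test_matches_exhaustive_minimum_on_four_leaves(self, rng):
        tops = all_rooted_topologies(list("ABCD"))
        for _ in range(5):
            trees = [tops[rng.integers(len(tops))] for _ in range(3)]
            res = build_supertree(trees)
            exhaustive = min(
                sum(spr_distance(c, t).k for t in trees) for c in tops
            )
            assert res.total_spr == exhaustive
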