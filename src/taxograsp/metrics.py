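"""Tree comparison: edit distance, Robinson–Foulds, and pair statistics.

The tree edit distance (TED) is the minimal total cost of node deletions,
insertions and label renames transforming one rooted tree into another.
The dynamic program operates on *ordered* trees, while the taxonomy trees
are unordered; both trees are therefore canonicalized first (children
sorted by their smallest descendant leaf label), making the comparison a
deterministic function of the unordered topologies.  Internal nodes all
carry one shared null label, so renames effectively act on leaves.  The DP
is the classic Zhang–Shasha keyroot decomposition, exact in
O(n^2 * depth^2).

Robinson–Foulds counts the clades present in exactly one of two trees on
the same leaf set; it is the planted-tree recovery metric of the synthetic
validation experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phylo import Node, PhyloTree

__all__ = ["EditCosts", "tree_edit_distance", "robinson_foulds", "pairwise_stats"]

NULL_LABEL = ""  # shared label of all internal nodes


@dataclass(frozen=True)
class EditCosts:
    c_delete: float = 1.0
    c_insert: float = 1.0
    c_rename: float = 1.0

    def __post_init__(self):
        if min(self.c_delete, self.c_insert, self.c_rename) < 0:
            raise ValueError("edit costs must be non-negative")

    def rename(self, a: str, b: str) -> float:
        return 0.0 if a == b else self.c_rename


def _postorder(node: Node, labels: list, lmld: list) -> int:
    """Append postorder labels; return index of this node.

    ``lmld[i]`` is the postorder index of the leftmost leaf descendant of
    node i (Zhang–Shasha's l()).
    """
    if isinstance(node, str):
        if not node:
            raise ValueError("unlabeled leaf")
        labels.append(node)
        lmld.append(len(labels) - 1)
        return len(labels) - 1
    first = None
    for child in node:
        idx = _postorder(child, labels, lmld)
        if first is None:
            first = lmld[idx]
    labels.append(NULL_LABEL)
    lmld.append(first)
    return len(labels) - 1


def _keyroots(lmld: list) -> list:
    seen = {}
    for i, l in enumerate(lmld):
        seen[l] = i  # last (highest) node with this leftmost leaf
    return sorted(seen.values())


def tree_edit_distance(t1: PhyloTree, t2: PhyloTree,
                       costs: EditCosts = EditCosts()) -> float:
    """Exact ordered tree edit distance between canonicalized trees.

    With the default unit costs the distance is 0 iff the canonical trees
    are identical.
    """
    lab1: list = []
    lml1: list = []
    _postorder(t1.root, lab1, lml1)
    lab2: list = []
    lml2: list = []
    _postorder(t2.root, lab2, lml2)
    n1, n2 = len(lab1), len(lab2)
    kr1, kr2 = _keyroots(lml1), _keyroots(lml2)

    cd, ci = costs.c_delete, costs.c_insert
    td = np.zeros((n1, n2))

    for i in kr1:
        for j in kr2:
            # forest distance over subforests rooted at keyroots i, j
            li, lj = lml1[i], lml2[j]
            m, n = i - li + 2, j - lj + 2
            fd = np.zeros((m, n))
            for x in range(1, m):
                fd[x, 0] = fd[x - 1, 0] + cd
            for y in range(1, n):
                fd[0, y] = fd[0, y - 1] + ci
            for x in range(1, m):
                for y in range(1, n):
                    a, b = li + x - 1, lj + y - 1
                    if lml1[a] == li and lml2[b] == lj:
                        fd[x, y] = min(
                            fd[x - 1, y] + cd,
                            fd[x, y - 1] + ci,
                            fd[x - 1, y - 1] + costs.rename(lab1[a], lab2[b]),
                        )
                        td[a, b] = fd[x, y]
                    else:
                        fd[x, y] = min(
                            fd[x - 1, y] + cd,
                            fd[x, y - 1] + ci,
                            fd[lml1[a] - li, lml2[b] - lj] + td[a, b],
                        )
    return float(td[n1 - 1, n2 - 1])


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> int:
    """Number of clades present in exactly one of the two trees."""
    if t1.leaves != t2.leaves:
        diff = sorted(t1.leaves ^ t2.leaves)
        raise ValueError(f"trees have different leaf sets; symmetric difference {diff}")
    return len(t1.clades() ^ t2.clades())


def pairwise_stats(trees, metric=tree_edit_distance) -> tuple:
    """Mean and SD of ``metric`` over all unordered pairs of ``trees``.

    The SD is the population standard deviation (ddof=0), so it is defined
    for a single pair as well.
    """
    trees = list(trees)
    if len(trees) < 2:
        raise ValueError("need at least two trees")
    values = [metric(a, b) for i, a in enumerate(trees) for b in trees[i + 1:]]
    return float(np.mean(values)), float(np.std(values))
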