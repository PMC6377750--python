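"""Agglomerative clustering of grasp distance matrices into rooted trees.

Grasps start as singleton clusters and the closest pair is merged
repeatedly until one cluster remains (bottom-up agglomeration); the merge
heights come from the configured linkage.  The default linkage is
``average`` (UPGMA), whose ultrametric output matches the downstream tree
model of all leaves equidistant from the root; ``single`` and ``complete``
are available for sensitivity runs.

Tie-breaking is explicit and deterministic because the supertree stage is
sensitive to it: among equal-distance candidate pairs, the pair whose
(lexicographically smallest member label, then the other cluster's
smallest label) is smallest is merged first.  The matrix -> tree map is
therefore a pure function.

The dendrogram (merges with heights) is then converted to a
:class:`~taxograsp.phylo.PhyloTree` by discarding the heights: an
unordered rooted binary tree with unweighted edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distance import GraspDistanceMatrix
from .phylo import PhyloTree

__all__ = ["Dendrogram", "agglomerate", "to_phylo", "LINKAGES"]

LINKAGES = ("average", "single", "complete")


@dataclass
class Dendrogram:
    """Ordered merge list; each entry is (members_a, members_b, height)."""

    merges: list  # [(frozenset, frozenset, float), ...]
    labels: tuple

    def __post_init__(self):
        if len(self.merges) != len(self.labels) - 1:
            raise ValueError("a dendrogram over G leaves must have G-1 merges")

    @property
    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h in self.merges])


def agglomerate(dmat: GraspDistanceMatrix, linkage: str = "average") -> Dendrogram:
    """Hierarchical agglomerative clustering of a grasp distance matrix."""
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    labels = tuple(dmat.labels)
    G = len(labels)
    if G < 2:
        raise ValueError("need at least two grasps to cluster")

    D = dmat.d.astype(float).copy()
    # active clusters: members (frozenset), size, smallest member label
    members = [frozenset([lab]) for lab in labels]
    sizes = [1] * G
    mins = list(labels)
    active = list(range(G))
    merges = []

    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                dij = D[i, j]
                tie_key = tuple(sorted((mins[i], mins[j])))
                key = (dij, tie_key)
                if best is None or key < best[0]:
                    best = (key, i, j)
        key, i, j = best
        merges.append((members[i], members[j], float(key[0])))

        # linkage update against all other active clusters
        ni, nj = sizes[i], sizes[j]
        for k in active:
            if k in (i, j):
                continue
            if linkage == "average":
                dk = (ni * D[i, k] + nj * D[j, k]) / (ni + nj)
            elif linkage == "single":
                dk = min(D[i, k], D[j, k])
            else:
                dk = max(D[i, k], D[j, k])
            D[i, k] = D[k, i] = dk
        members[i] = members[i] | members[j]
        sizes[i] = ni + nj
        mins[i] = min(mins[i], mins[j])
        active.remove(j)

    return Dendrogram(merges=merges, labels=labels)


def to_phylo(dend: Dendrogram) -> PhyloTree:
    """Convert a dendrogram to an unordered rooted unweighted binary tree."""
    nodes = {frozenset([lab]): lab for lab in dend.labels}
    node = None
    for a, b, _height in dend.merges:
        node = (nodes.pop(a), nodes.pop(b))
        nodes[a | b] = node
    return PhyloTree(node)


def cophenetic_matrix(dend: Dendrogram) -> np.ndarray:
    """Pairwise merge heights (the cophenetic distances), in label order."""
    index = {lab: i for i, lab in enumerate(dend.labels)}
    G = len(dend.labels)
    C = np.zeros((G, G))
    for a, b, h in dend.merges:
        for la in a:
            for lb in b:
                C[index[la], index[lb]] = C[index[lb], index[la]] = h
    return C
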