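"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written against the *definitions* of the
quantities (exhaustive enumeration, explicit double loops) rather than the
package's algorithms, so agreement is evidence of correctness and not of
shared bugs.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np

from taxograsp.phylo import PhyloTree

# ---------------------------------------------------------------------------
# tree generation / enumeration
# ---------------------------------------------------------------------------


def _positions(t, prefix=()):
    yield prefix
    if not isinstance(t, str):
        for i, c in enumerate(t):
            yield from _positions(c, prefix + (i,))


def _get(t, p):
    for i in p:
        t = t[i]
    return t


def _replace(t, p, new):
    if not p:
        return new
    return tuple(_replace(c, p[1:], new) if j == p[0] else c
                 for j, c in enumerate(t))


def _remove(t, p):
    parent_path = p[:-1]
    parent = _get(t, parent_path)
    sibs = tuple(c for j, c in enumerate(parent) if j != p[-1])
    return _replace(t, parent_path, sibs[0] if len(sibs) == 1 else sibs)


def _insert(t, path, node):
    if not path:
        return (t, node)
    i = path[0]
    return tuple(_insert(c, path[1:], node) if j == i else c
                 for j, c in enumerate(t))


def all_rooted_topologies(labels):
    """Every rooted binary topology over ``labels``, by leaf insertion."""
    labels = list(labels)
    trees = [labels[0]]
    for lab in labels[1:]:
        trees = [_insert(t, pos, lab) for t in trees for pos in _positions(t)]
    return [PhyloTree(t) for t in trees]


def random_topology(rng, labels) -> PhyloTree:
    """A uniformly random rooted binary topology (by random leaf insertion)."""
    labels = list(labels)
    t = labels[0]
    for lab in labels[1:]:
        pos = list(_positions(t))
        t = _insert(t, pos[rng.integers(len(pos))], lab)
    return PhyloTree(t)


# ---------------------------------------------------------------------------
# SPR: independent neighbourhood + BFS distance
# ---------------------------------------------------------------------------


def spr_neighbors_oracle(tree: PhyloTree) -> set:
    """All trees one rooted SPR move away (fresh enumeration code)."""
    out = set()
    root = tree.root
    if isinstance(root, str):
        return out
    for ppath in list(_positions(root))[1:]:
        sub = _get(root, ppath)
        rem = _remove(root, ppath)
        for gpath in _positions(rem):
            tgt = _get(rem, gpath)
            cand = PhyloTree(_replace(rem, gpath, (tgt, sub)))
            if cand.root != root:
                out.add(cand)
    return out


class SprSpace:
    """Precomputed SPR adjacency over all topologies on one leaf set."""

    def __init__(self, labels):
        self.tops = all_rooted_topologies(labels)
        self.adj = {t.root: [n.root for n in spr_neighbors_oracle(t)]
                    for t in self.tops}

    def bfs_distance(self, t1: PhyloTree, t2: PhyloTree) -> int:
        a, b = t1.root, t2.root
        if a == b:
            return 0
        seen = {a}
        queue = deque([(a, 0)])
        while queue:
            x, d = queue.popleft()
            for y in self.adj[x]:
                if y == b:
                    return d + 1
                if y not in seen:
                    seen.add(y)
                    queue.append((y, d + 1))
        raise RuntimeError("SPR space is connected; unreachable")


# ---------------------------------------------------------------------------
# tree edit distance: exhaustive valid-mapping search
# ---------------------------------------------------------------------------


def _preorder_nodes(root):
    """(label, descendant-range) per node in preorder; range = (lo, hi]."""
    labels = []
    ranges = []

    def rec(node):
        idx = len(labels)
        labels.append(node if isinstance(node, str) else "")
        ranges.append(None)
        if not isinstance(node, str):
            for c in node:
                rec(c)
        ranges[idx] = (idx, len(labels))  # node's subtree = preorder [idx, hi)
        return idx

    rec(root)
    return labels, ranges


def ted_mapping_oracle(t1: PhyloTree, t2: PhyloTree, c_delete=1.0, c_insert=1.0,
                       c_rename=1.0) -> float:
    """Minimal edit cost over all valid ordered-tree mappings.

    A mapping is a one-to-one pairing preserving ancestorship and
    left-to-right order; its cost is the rename cost of paired nodes plus
    deletion/insertion of unpaired ones.  Exponential: use on tiny trees.
    """
    lab1, rng1 = _preorder_nodes(t1.root)
    lab2, rng2 = _preorder_nodes(t2.root)
    n1, n2 = len(lab1), len(lab2)

    def anc(ranges, a, b):  # a strict ancestor of b
        lo, hi = ranges[a]
        return a != b and lo <= b < hi

    best = [c_delete * n1 + c_insert * n2]

    def rec(i, used2, pairs, cost):
        if cost >= best[0]:
            return
        if i == n1:
            remaining = n2 - len(pairs)
            total = cost + c_insert * remaining
            if total < best[0]:
                best[0] = total
            return
        # leave node i unmapped
        rec(i + 1, used2, pairs, cost + c_delete)
        for j in range(n2):
            if used2 & (1 << j):
                continue
            ok = True
            for (pi, pj) in pairs:
                if anc(rng1, pi, i) != anc(rng2, pj, j):
                    ok = False
                    break
                if anc(rng1, i, pi) != anc(rng2, j, pj):
                    ok = False
                    break
                if not anc(rng1, pi, i) and not anc(rng1, i, pi):
                    if (pi < i) != (pj < j):
                        ok = False
                        break
            if ok:
                rename = 0.0 if lab1[i] == lab2[j] else c_rename
                rec(i + 1, used2 | (1 << j), pairs + [(i, j)], cost + rename)

    rec(0, 0, [], 0.0)
    return best[0]


# ---------------------------------------------------------------------------
# Mahalanobis: explicit double-loop pooled covariance
# ---------------------------------------------------------------------------


def mahalanobis_oracle(X: np.ndarray, group_of_row, group_ids) -> np.ndarray:
    """G x G Mahalanobis matrix computed with explicit loops."""
    X = np.asarray(X, dtype=float)
    group_of_row = np.asarray(group_of_row)
    p = X.shape[1]
    means = {}
    for g in group_ids:
        rows = X[group_of_row == g]
        means[g] = rows.mean(axis=0)
    W = np.zeros((p, p))
    N = 0
    for g in group_ids:
        rows = X[group_of_row == g]
        N += rows.shape[0]
        for r in rows:
            diff = r - means[g]
            for a in range(p):
                for b in range(p):
                    W[a, b] += diff[a] * diff[b]
    W /= N - len(group_ids)
    Winv = np.linalg.inv(W)
    G = len(group_ids)
    D = np.zeros((G, G))
    for i, gi in enumerate(group_ids):
        for j, gj in enumerate(group_ids):
            d = means[gi] - means[gj]
            D[i, j] = np.sqrt(max(d @ Winv @ d, 0.0))
    return D
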