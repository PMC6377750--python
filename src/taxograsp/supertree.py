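"""Rooted-SPR distances and SPR supertrees via maximum agreement forests.

The distance between two rooted binary trees on one leaf set is the
minimum number of subtree prune-and-regraft (SPR) moves turning one into
the other.  It equals the number of components of a *maximum agreement
forest* (MAF) of the two trees minus one, computed here on the
rho-augmented trees (a pendant handle leaf attached above each root, the
standard device that makes the forest/move correspondence exact for
rooted trees).

``spr_distance`` performs an exact iterative-deepening search over
edge-cutting possibilities: for k = 0, 1, 2, ... it tries every set of k
edges of the second tree, cuts them, and checks whether the resulting
forest is an agreement forest with the first tree (every component's
topology equals the first tree's restriction to its leaves, and the
components' spanning subtrees are pairwise vertex-disjoint in the first
tree).  The search is exponential in k but exact; beyond ``k_max`` a
greedy forest provides a flagged upper bound.

``build_supertree`` merges a collection of trees sharing one leaf set:
phase 1 seeds the supertree with the input tree of minimal total SPR
distance to the others; phase 2 hill-climbs over all SPR rearrangements of
the current supertree, at each step taking the move that most reduces the
total distance, until no move improves.  With a shared leaf set the
cluster-decomposition step of the general (partial-overlap) supertree
problem is a no-op, so it is not implemented; the entry point would be the
natural hook if partial overlap were ever needed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .phylo import Node, PhyloTree

__all__ = ["MAFResult", "SupertreeResult", "spr_distance", "spr_neighbors",
           "build_supertree"]

RHO = "\x00rho"  # reserved handle-leaf label for root augmentation


# ---------------------------------------------------------------------------
# indexed trees: flat arrays for cheap cutting / restriction / spanning checks
# ---------------------------------------------------------------------------

class _Indexed:
    __slots__ = ("children", "parent", "label", "depth", "root", "leaf_index")

    def __init__(self, root: Node):
        self.children: list = []
        self.parent: list = []
        self.label: list = []
        self.depth: list = []
        self.leaf_index: dict = {}
        self.root = self._build(root, -1, 0)

    def _build(self, node: Node, parent: int, depth: int) -> int:
        idx = len(self.children)
        self.children.append([])
        self.parent.append(parent)
        self.depth.append(depth)
        if isinstance(node, str):
            self.label.append(node)
            self.leaf_index[node] = idx
        else:
            self.label.append(None)
            # placeholder; children appended below
            for child in node:
                cidx = self._build(child, idx, depth + 1)
                self.children[idx].append(cidx)
        return idx

    def n_nodes(self) -> int:
        return len(self.children)

    def restrict(self, keep: frozenset) -> Node | None:
        """Topology of the tree restricted to leaf labels in ``keep``."""

        def rec(v: int) -> Node | None:
            if self.label[v] is not None:
                return self.label[v] if self.label[v] in keep else None
            kids = [r for r in (rec(c) for c in self.children[v]) if r is not None]
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]
            return tuple(kids)

        return rec(self.root)

    def spanning_nodes(self, leaves: frozenset) -> set:
        """Node set of the minimal subtree connecting ``leaves``."""
        idxs = [self.leaf_index[l] for l in leaves]
        if len(idxs) == 1:
            return {idxs[0]}
        # LCA by repeated pairwise climbing
        lca = idxs[0]
        for v in idxs[1:]:
            a, b = lca, v
            while self.depth[a] > self.depth[b]:
                a = self.parent[a]
            while self.depth[b] > self.depth[a]:
                b = self.parent[b]
            while a != b:
                a = self.parent[a]
                b = self.parent[b]
            lca = a
        nodes = {lca}
        for v in idxs:
            while v != lca and v not in nodes:
                nodes.add(v)
                v = self.parent[v]
        return nodes


def _canonical(node: Node) -> Node:
    return PhyloTree(node).root if not isinstance(node, str) else node


def _leafset(node: Node) -> frozenset:
    if isinstance(node, str):
        return frozenset([node])
    out: set = set()
    stack = [node]
    while stack:
        n = stack.pop()
        if isinstance(n, str):
            out.add(n)
        else:
            stack.extend(n)
    return frozenset(out)


# ---------------------------------------------------------------------------
# agreement-forest machinery
# ---------------------------------------------------------------------------

def _cut_components(t2: _Indexed, cut: tuple) -> list | None:
    """Components (as canonical Node tuples) after cutting edges above ``cut``.

    Returns None if some cut is wasted (produces an empty component).
    """
    cutset = set(cut)

    def build(v: int) -> Node | None:
        if t2.label[v] is not None:
            return t2.label[v]
        kids = [r for c in t2.children[v] if c not in cutset
                for r in [build(c)] if r is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        return tuple(kids)

    comps = []
    for v in [t2.root] + sorted(cutset):
        comp = build(v)
        if comp is None:
            return None
        comps.append(comp)
    return comps


def _is_agreement_forest(parts: list, t1: _Indexed, t2: _Indexed | None) -> bool:
    """Check whether components ``parts`` form an agreement forest.

    ``parts`` are Node tuples whose leaf sets partition the leaves.  Checks
    restriction equality and spanning-subtree disjointness against ``t1``
    (and against ``t2`` too when given — needed when the partition did not
    come from cutting ``t2`` itself).
    """
    seen1: set = set()
    seen2: set = set()
    for comp in parts:
        leaves = _leafset(comp)
        r1 = t1.restrict(leaves)
        if r1 is None or _canonical(r1) != _canonical(comp):
            return False
        span1 = t1.spanning_nodes(leaves)
        if seen1 & span1:
            return False
        seen1 |= span1
        if t2 is not None:
            if _canonical(t2.restrict(leaves)) != _canonical(comp):
                return False
            span2 = t2.spanning_nodes(leaves)
            if seen2 & span2:
                return False
            seen2 |= span2
    return True


@dataclass(frozen=True)
class MAFResult:
    """An agreement forest between two trees and the SPR distance it yields.

    ``components`` are the leaf sets of the forest (handle leaf stripped);
    ``k`` is the number of edge cuts, equal to the rooted SPR distance when
    ``exact`` is True and an upper bound otherwise.
    """

    components: tuple
    k: int
    exact: bool = True


def _check_pair(t1: PhyloTree, t2: PhyloTree) -> None:
    if t1.leaves != t2.leaves:
        diff = sorted(t1.leaves ^ t2.leaves)
        raise ValueError(f"trees have different leaf sets; symmetric difference {diff}")
    if not (t1.is_binary() and t2.is_binary()):
        raise ValueError("both trees must be binary")
    if RHO in t1.leaves:
        raise ValueError("reserved label in tree")


def _strip_rho(comps) -> tuple:
    out = []
    for c in comps:
        leaves = _leafset(c) - {RHO}
        if leaves:
            out.append(leaves)
    return tuple(sorted(out, key=lambda s: sorted(s)))


def _greedy_forest(t1: _Indexed, t2: _Indexed, all_leaves: frozenset) -> list:
    """Any valid agreement forest, built by splitting off singleton leaves."""
    t2_tuple = _canonical_from_indexed(t2)
    parts = [t2_tuple]
    while not _is_agreement_forest(parts, t1, t2):
        # split the first offending multi-leaf part
        for i, comp in enumerate(parts):
            leaves = _leafset(comp)
            if len(leaves) < 2:
                continue
            if not _is_agreement_forest([comp], t1, t2) or \
               not _is_agreement_forest(parts[: i + 1], t1, t2):
                drop = min(leaves - {RHO}, default=None) or min(leaves)
                rest = leaves - {drop}
                new_comp = t2.restrict(rest)
                parts[i] = new_comp
                parts.append(drop)
                break
        else:  # fall back: split the largest part
            i = max(range(len(parts)), key=lambda j: len(_leafset(parts[j])))
            leaves = _leafset(parts[i])
            drop = min(leaves - {RHO}, default=None) or min(leaves)
            parts[i] = t2.restrict(leaves - {drop})
            parts.append(drop)
    return parts


def _canonical_from_indexed(t: _Indexed) -> Node:
    def build(v):
        if t.label[v] is not None:
            return t.label[v]
        return tuple(build(c) for c in t.children[v])

    return build(t.root)


def spr_distance(t1: PhyloTree, t2: PhyloTree, k_max: int = 12) -> MAFResult:
    """Exact rooted SPR distance between two binary trees on one leaf set.

    Iterative deepening over the number of cut edges k; for each k every
    k-subset of edges of ``t2`` (rho-augmented) is tried.  If no agreement
    forest of at most ``k_max`` cuts exists, a greedy forest is returned
    with ``exact=False`` (an upper bound).
    """
    _check_pair(t1, t2)
    if t1 == t2:
        return MAFResult(components=(frozenset(t1.leaves),), k=0, exact=True)

    aug1 = _Indexed((t1.root, RHO))
    aug2 = _Indexed((t2.root, RHO))
    edges = [v for v in range(aug2.n_nodes()) if v != aug2.root]

    for k in range(1, k_max + 1):
        for cut in itertools.combinations(edges, k):
            comps = _cut_components(aug2, cut)
            if comps is None:
                continue
            if _is_agreement_forest(comps, aug1, None):
                return MAFResult(components=_strip_rho(comps), k=k, exact=True)

    parts = _greedy_forest(aug1, aug2, t1.leaves | {RHO})
    return MAFResult(components=_strip_rho(parts), k=len(parts) - 1, exact=False)


# ---------------------------------------------------------------------------
# SPR rearrangements
# ---------------------------------------------------------------------------

def _all_paths(node: Node, prefix=()):  # all node positions, preorder
    yield prefix
    if not isinstance(node, str):
        for i, child in enumerate(node):
            yield from _all_paths(child, prefix + (i,))


def _get(node: Node, path) -> Node:
    for i in path:
        node = node[i]
    return node


def _replace(node: Node, path, new: Node) -> Node:
    if not path:
        return new
    i = path[0]
    return tuple(
        _replace(c, path[1:], new) if j == i else c for j, c in enumerate(node)
    )


def spr_neighbors(tree: PhyloTree) -> list:
    """All distinct trees one rooted SPR move away, in canonical order.

    Every proper subtree is pruned in turn (preorder) and regrafted onto
    every edge of the remaining tree, including the edge above the root
    (which makes the pruned subtree a sibling of everything else).  The
    original topology is excluded; duplicates are removed preserving first
    occurrence, so the enumeration order is deterministic.
    """
    if isinstance(tree.root, str):
        return []
    root = tree.root
    out: dict = {}
    for prune_path in _all_paths(root):
        if not prune_path:
            continue  # cannot prune the root
        pruned = _get(root, prune_path)
        # remove: replace parent with the pruned node's sibling
        parent_path = prune_path[:-1]
        parent = _get(root, parent_path)
        siblings = tuple(c for j, c in enumerate(parent) if j != prune_path[-1])
        remaining = _replace(root, parent_path,
                             siblings[0] if len(siblings) == 1 else siblings)
        for graft_path in _all_paths(remaining):
            target = _get(remaining, graft_path)
            candidate = _replace(remaining, graft_path, (target, pruned))
            t = PhyloTree(candidate)
            if t.root != root and t.root not in out:
                out[t.root] = t
    return list(out.values())


@dataclass
class SupertreeResult:
    """Supertree minimizing total SPR distance, with its search trace."""

    tree: PhyloTree
    total_spr: int
    trace: list = field(default_factory=list)
    exact: bool = True


def build_supertree(trees, k_max: int = 12, max_iter: int = 100) -> SupertreeResult:
    """Merge rooted binary trees on one leaf set into an SPR supertree.

    Phase 1 picks, among the inputs, the tree with minimal total SPR
    distance to the others (ties broken by lowest index).  Phase 2
    repeatedly applies the SPR rearrangement of the current supertree that
    most reduces the total distance (first-best among equal improvements,
    moves enumerated canonically), stopping when no move improves or after
    ``max_iter`` accepted moves.  Deterministic.
    """
    trees = list(trees)
    if not trees:
        raise ValueError("need at least one input tree")
    leaves = trees[0].leaves
    for t in trees[1:]:
        if t.leaves != leaves:
            diff = sorted(t.leaves ^ leaves)
            raise ValueError(f"input trees disagree on leaves: {diff}")

    memo: dict = {}
    inexact = [False]

    def dist(a: PhyloTree, b: PhyloTree) -> int:
        key = (a.root, b.root) if hash(a.root) <= hash(b.root) else (b.root, a.root)
        if key not in memo:
            res = spr_distance(a, b, k_max=k_max)
            if not res.exact:
                inexact[0] = True
            memo[key] = res.k
        return memo[key]

    def total(t: PhyloTree) -> int:
        return sum(dist(t, other) for other in trees)

    totals = [total(t) for t in trees]
    best_idx = min(range(len(trees)), key=lambda i: (totals[i], i))
    current = trees[best_idx]
    cur_total = totals[best_idx]
    trace = [{"phase": 1, "tree": current.newick(), "total_spr": cur_total,
              "seed_index": best_idx}]

    for _ in range(max_iter):
        best_total = cur_total
        best_tree = None
        for nb in spr_neighbors(current):
            t = total(nb)
            if t < best_total:
                best_total = t
                best_tree = nb
        if best_tree is None:
            break
        current, cur_total = best_tree, best_total
        trace.append({"phase": 2, "tree": current.newick(), "total_spr": cur_total})

    return SupertreeResult(tree=current, total_spr=cur_total, trace=trace,
                           exact=not inexact[0])
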