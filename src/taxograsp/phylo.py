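"""Rooted, unordered, unweighted, leaf-labelled trees.

Every hierarchy handled by the taxonomy pipeline — per-subject dendrogram
topologies, feature supertrees, modality taxonomies, the general taxonomy —
is a rooted tree with unweighted edges, anonymous internal nodes and
uniquely labelled leaves (the grasp names).

Trees are kept in *canonical form*: the children of every internal node are
ordered by the smallest leaf label found below them.  Because leaf labels
are unique, this ordering is total, so structural equality, hashing,
Newick serialisation and the ordered tree-edit comparison are all
deterministic functions of the unordered topology.

The underlying node representation is deliberately primitive: a leaf is its
label (a ``str``) and an internal node is a ``tuple`` of child nodes.  This
makes trees immutable and hashable, which the supertree search relies on.
"""

from __future__ import annotations

from typing import Iterator, Union

Node = Union[str, tuple]
__all__ = ["PhyloTree", "Node"]


def _min_leaf(node: Node) -> str:
    while not isinstance(node, str):
        node = min(node, key=_min_leaf)
    return node


def _canonicalize(node: Node) -> Node:
    if isinstance(node, str):
        return node
    return tuple(sorted((_canonicalize(c) for c in node), key=_min_leaf))


def _collect_leaves(node: Node, out: list) -> None:
    if isinstance(node, str):
        out.append(node)
    else:
        for c in node:
            _collect_leaves(c, out)


def _to_newick(node: Node) -> str:
    if isinstance(node, str):
        return node
    return "(" + ",".join(_to_newick(c) for c in node) + ")"


class PhyloTree:
    """A rooted unordered tree with unweighted edges and labelled leaves.

    Parameters
    ----------
    root
        Nested node structure: a leaf label, or a tuple of child nodes.

    Raises
    ------
    ValueError
        If a leaf label is empty, labels are duplicated, or an internal
        node has fewer than two children.
    """

    __slots__ = ("root", "_leaves")

    def __init__(self, root: Node):
        self._validate(root)
        self.root: Node = _canonicalize(root)
        leaves: list = []
        _collect_leaves(self.root, leaves)
        if len(set(leaves)) != len(leaves):
            dupes = sorted({l for l in leaves if leaves.count(l) > 1})
            raise ValueError(f"duplicate leaf labels: {dupes}")
        self._leaves = frozenset(leaves)

    @staticmethod
    def _validate(node: Node) -> None:
        if isinstance(node, str):
            if not node:
                raise ValueError("leaf labels must be non-empty strings")
            return
        if not isinstance(node, tuple):
            raise TypeError(f"tree nodes must be str or tuple, got {type(node)!r}")
        if len(node) < 2:
            raise ValueError("internal nodes must have at least two children")
        for c in node:
            PhyloTree._validate(c)

    # -- basic queries ----------------------------------------------------

    @property
    def leaves(self) -> frozenset:
        """The set of leaf labels."""
        return self._leaves

    @property
    def n_leaves(self) -> int:
        return len(self._leaves)

    def is_binary(self) -> bool:
        """True if every internal node has exactly two children."""

        def check(node: Node) -> bool:
            if isinstance(node, str):
                return True
            return len(node) == 2 and all(check(c) for c in node)

        return check(self.root)

    def subtrees(self) -> Iterator[Node]:
        """Yield every node (as its nested representation), preorder."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            if not isinstance(node, str):
                stack.extend(reversed(node))

    def n_nodes(self) -> int:
        return sum(1 for _ in self.subtrees())

    def clades(self) -> set:
        """Leaf sets of all internal nodes (the root included).

        The symmetric difference of two trees' clade sets is the
        Robinson–Foulds distance used for planted-tree recovery checks.
        """
        out = set()
        for node in self.subtrees():
            if not isinstance(node, str):
                leaves: list = []
                _collect_leaves(node, leaves)
                out.add(frozenset(leaves))
        return out

    # -- transformations --------------------------------------------------

    def restrict(self, keep) -> "PhyloTree":
        """Restriction to a subset of leaves (degree-2 nodes suppressed)."""
        keep = frozenset(keep)
        missing = keep - self._leaves
        if missing:
            raise ValueError(f"labels not in tree: {sorted(missing)}")

        def rec(node: Node):
            if isinstance(node, str):
                return node if node in keep else None
            kids = [r for r in (rec(c) for c in node) if r is not None]
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]
            return tuple(kids)

        sub = rec(self.root)
        if sub is None:
            raise ValueError("restriction to an empty leaf set")
        return PhyloTree(sub)

    def relabel(self, mapping: dict) -> "PhyloTree":
        """Return a copy with leaf labels replaced via ``mapping``."""

        def rec(node: Node):
            if isinstance(node, str):
                return mapping.get(node, node)
            return tuple(rec(c) for c in node)

        return PhyloTree(rec(self.root))

    # -- serialisation ----------------------------------------------------

    def newick(self) -> str:
        """Canonical Newick string, branch lengths omitted."""
        if isinstance(self.root, str):
            return self.root + ";"
        return _to_newick(self.root) + ";"

    # -- dunder -----------------------------------------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, PhyloTree):
            return NotImplemented
        return self.root == other.root

    def __hash__(self) -> int:
        return hash(self.root)

    def __repr__(self) -> str:
        return f"PhyloTree({self.newick()!r})"
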