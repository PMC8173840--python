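"""Lightweight unrooted phylogenetic trees.

Trees are stored as a rooted structure whose root is an internal node with
three (or more) children — the standard unrooted-binary convention.  For
reversible models the placement of this node is immaterial; for the
nonstationary model it is the node where the root base frequencies apply,
so callers who care (outgroup rooting) should build the tree accordingly.

Newick parsing/serialization goes through dendropy; the in-memory structure
is a minimal node class so the likelihood engines can attach per-branch
parameters by node id without fighting a heavyweight API.
"""

from __future__ import annotations

import numpy as np
import dendropy


class Node:
    __slots__ = ("name", "length", "children", "parent", "id")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.length = float(length)
        self.children: list["Node"] = []
        self.parent: "Node | None" = None
        self.id: int = -1

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Tree:
    """Unrooted tree with named leaves and branch lengths on child edges."""

    def __init__(self, root: Node):
        self.root = root
        self._reindex()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dt = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        if len(dt.seed_node.child_nodes()) == 2 and any(
            not c.is_leaf() for c in dt.seed_node.child_nodes()
        ):
            dt.deroot()

        def build(dn) -> Node:
            node = Node(
                name=dn.taxon.label if dn.taxon else None,
                length=dn.edge.length or 0.0,
            )
            for c in dn.child_nodes():
                node.add(build(c))
            return node

        return cls(build(dt.seed_node))

    def copy(self) -> "Tree":
        def dup(n: Node) -> Node:
            m = Node(n.name, n.length)
            for c in n.children:
                m.add(dup(c))
            return m

        return Tree(dup(self.root))

    # -- traversal ----------------------------------------------------

    def _reindex(self) -> None:
        for i, n in enumerate(self.postorder()):
            n.id = i

    def postorder(self) -> list[Node]:
        out: list[Node] = []

        def walk(n: Node) -> None:
            for c in n.children:
                walk(c)
            out.append(n)

        walk(self.root)
        return out

    def nodes(self) -> list[Node]:
        return self.postorder()

    def node_by_id(self, node_id: int) -> Node:
        for n in self.postorder():
            if n.id == node_id:
                return n
        raise KeyError(node_id)

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def internal_edge_ids(self) -> list[int]:
        """Ids of child nodes whose parent edge is internal (both ends
        internal nodes)."""
        return [
            n.id
            for n in self.postorder()
            if not n.is_leaf and n.parent is not None
        ]

    # -- serialization ------------------------------------------------

    def to_newick(self) -> str:
        def fmt(n: Node) -> str:
            if n.is_leaf:
                return f"{n.name}:{n.length:.10g}"
            inner = ",".join(fmt(c) for c in n.children)
            if n.parent is None:
                return f"({inner})"
            return f"({inner}):{n.length:.10g}"

        return fmt(self.root) + ";"

    # -- topology identity --------------------------------------------

    def splits(self) -> frozenset[frozenset[str]]:
        """Nontrivial bipartitions, each normalized to the side not
        containing the alphabetically first leaf."""
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        out = set()

        def walk(n: Node) -> frozenset:
            if n.is_leaf:
                return frozenset([n.name])
            below = frozenset().union(*(walk(c) for c in n.children))
            if n.parent is not None and 1 < len(below) < len(all_leaves) - 1:
                side = below if ref not in below else all_leaves - below
                out.add(side)
            return below

        walk(self.root)
        return frozenset(out)

    def same_topology(self, other: "Tree") -> bool:
        return (
            set(self.leaf_names()) == set(other.leaf_names())
            and self.splits() == other.splits()
        )


def random_topology(
    leaf_names: list[str],
    rng: np.random.Generator,
    branch_length: float | tuple[float, float] = (0.05, 0.4),
) -> Tree:
    """Random unrooted binary topology by sequential edge attachment.

    Branch lengths are drawn uniformly from ``branch_length`` when a range
    is given, else set to the constant provided.
    """
    if len(leaf_names) < 3:
        raise ValueError("need at least 3 leaves")

    def bl() -> float:
        if isinstance(branch_length, tuple):
            return float(rng.uniform(*branch_length))
        return float(branch_length)

    root = Node()
    for name in leaf_names[:3]:
        root.add(Node(name, bl()))
    tree = Tree(root)
    for name in leaf_names[3:]:
        # attach on a uniformly chosen existing edge
        candidates = [n for n in tree.postorder() if n.parent is not None]
        target = candidates[rng.integers(len(candidates))]
        parent = target.parent
        mid = Node(length=bl())
        parent.children[parent.children.index(target)] = mid
        mid.parent = parent
        mid.add(target)
        target.length = bl()
        mid.add(Node(name, bl()))
        tree = Tree(tree.root)
    return tree


def regraft_leaf(tree: Tree, leaf_name: str, target_edge_index: int) -> Tree:
    """Return a copy with ``leaf_name`` pruned and re-attached onto the
    middle of an edge of the pruned tree.

    ``target_edge_index`` indexes the pruned tree's edges in postorder
    (taken modulo the edge count), so sweeping it enumerates alternative
    placements of one taxon — e.g. a symbiont regrafted onto different
    candidate clades.
    """
    t = tree.copy()
    leaf = next(n for n in t.leaves() if n.name == leaf_name)
    parent = leaf.parent
    if parent is None:
        raise ValueError("cannot regraft the root")
    # prune: remove leaf, then splice out its degree-2 parent
    parent.children.remove(leaf)
    if len(parent.children) == 1 and parent.parent is not None:
        child = parent.children[0]
        child.length += parent.length
        gp = parent.parent
        gp.children[gp.children.index(parent)] = child
        child.parent = gp
    elif len(parent.children) == 2 and parent.parent is None:
        # root became degree-2: merge into one of its internal children
        internal = next(
            (c for c in parent.children if not c.is_leaf), parent.children[0]
        )
        other = next(c for c in parent.children if c is not internal)
        if internal.is_leaf:
            raise ValueError("tree too small to regraft")
        internal.children.append(other)
        other.parent = internal
        other.length += internal.length
        internal.parent = None
        internal.length = 0.0
        t = Tree(internal)
    t._reindex()
    edges = [n for n in t.postorder() if n.parent is not None]
    target = edges[target_edge_index % len(edges)]
    parent = target.parent
    mid = Node(length=target.length / 2)
    parent.children[parent.children.index(target)] = mid
    mid.parent = parent
    target.length = target.length / 2
    mid.add(target)
    mid.add(Node(leaf.name, leaf.length or 0.1))
    return Tree(t.root)
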