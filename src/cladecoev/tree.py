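"""Rooted phylogenetic trees over named taxa.

The tree class here is deliberately small: leaf-labelled rooted trees with
unlabelled internal nodes, enough structure to score parsimony, take
bipartitions and re-root on an outgroup.  Newick parsing is delegated to
dendropy; writing is done directly so that label quoting and the absence of
branch lengths stay under our control.
"""

from __future__ import annotations

import re
from typing import Iterable, Iterator

import dendropy

from .errors import ContractError, ValidationError

_SAFE_LABEL = re.compile(r"^[A-Za-z0-9_.+-]+$")


def _quote(label: str) -> str:
    if _SAFE_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


class Node:
    """A node of a rooted tree: a leaf (with label) or an internal node."""

    __slots__ = ("label", "children")

    def __init__(self, label: str | None = None, children: list["Node"] | None = None):
        self.label = label
        self.children: list[Node] = children if children is not None else []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r})" if self.is_leaf else f"Node<{len(self.children)}>"


class PhyloTree:
    """A rooted tree whose leaves are taxon labels.

    Internal nodes of degree >= 3 are permitted (consensus trees); most
    operations that require a binary tree check and raise ``ContractError``.
    """

    def __init__(self, root: Node):
        self.root = root
        labels = self.leaf_labels()
        if len(labels) != len(set(labels)):
            raise ValidationError("duplicate leaf labels in tree")
        if not labels:
            raise ValidationError("tree has no leaves")

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(data=newick, schema="newick",
                                      preserve_underscores=True)
        except Exception as exc:
            raise ValidationError(f"could not parse newick: {exc}")

        def conv(dnode) -> Node:
            if dnode.is_leaf():
                if dnode.taxon is None or dnode.taxon.label is None:
                    raise ValidationError("unlabelled leaf in newick input")
                return Node(label=dnode.taxon.label)
            return Node(children=[conv(c) for c in dnode.child_nodes()])

        return cls(conv(dtree.seed_node))

    def newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                return _quote(node.label)
            return "(" + ",".join(fmt(c) for c in node.children) + ")"

        return fmt(self.root) + ";"

    def __str__(self) -> str:
        return self.newick()

    # -------------------------------------------------------------- queries

    def leaf_labels(self) -> list[str]:
        """Leaf labels in tree (left-to-right) order."""
        out: list[str] = []

        def walk(node: Node) -> None:
            if node.is_leaf:
                out.append(node.label)
            else:
                for c in node.children:
                    walk(c)

        walk(self.root)
        return out

    @property
    def taxa(self) -> frozenset:
        return frozenset(self.leaf_labels())

    def is_binary(self) -> bool:
        def ok(node: Node) -> bool:
            if node.is_leaf:
                return True
            return len(node.children) == 2 and all(ok(c) for c in node.children)

        return ok(self.root)

    def postorder(self) -> Iterator[Node]:
        stack = [(self.root, False)]
        while stack:
            node, seen = stack.pop()
            if node.is_leaf or seen:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def clades(self, include_trivial: bool = False) -> list[frozenset]:
        """Leaf sets of internal nodes below the root (rooted clades).

        Trivial clades (single leaves and the full leaf set) are excluded
        unless requested.
        """
        n = len(self.taxa)
        out: list[frozenset] = []

        def walk(node: Node) -> frozenset:
            if node.is_leaf:
                s = frozenset([node.label])
            else:
                s = frozenset().union(*(walk(c) for c in node.children))
            if include_trivial or 1 < len(s) < n:
                out.append(s)
            return s

        walk(self.root)
        return out

    def bipartitions(self) -> frozenset:
        """Non-trivial splits of the *unrooted* topology.

        Each split is canonicalised as the side not containing the
        lexicographically smallest taxon, so two trees describe the same
        unrooted topology iff their bipartition sets are equal.
        """
        labels = self.taxa
        ref = min(labels)
        n = len(labels)
        splits = set()
        for clade in self.clades(include_trivial=False):
            side = clade if ref not in clade else labels - clade
            if 2 <= len(side) <= n - 2:
                splits.add(side)
        return frozenset(splits)

    def topology_key(self) -> frozenset:
        """Hashable identity of the unrooted topology."""
        return self.bipartitions()

    def contains_clade(self, clade: Iterable) -> bool:
        """True if ``clade`` is a (rooted) clade of this tree."""
        clade = frozenset(clade)
        return clade in set(self.clades(include_trivial=True))

    def contains_split(self, side: Iterable) -> bool:
        """True if the unrooted topology contains the given bipartition."""
        side = frozenset(side)
        labels = self.taxa
        ref = min(labels)
        canon = side if ref not in side else labels - side
        return canon in self.bipartitions()

    # ------------------------------------------------------------ rerooting

    def rooted_on(self, outgroup: str) -> "PhyloTree":
        """Return a copy rooted on the terminal edge of ``outgroup``.

        The root of the result has exactly two children: the outgroup leaf
        and the ingroup subtree.  Degree-two pass-through nodes created by
        removing the old root are suppressed.
        """
        if outgroup not in self.taxa:
            raise ContractError(f"outgroup {outgroup!r} is not a leaf of the tree")
        # Build an undirected adjacency over fresh node ids.
        nodes: list[str | None] = []
        adj: list[list[int]] = []

        def add(label: str | None) -> int:
            nodes.append(label)
            adj.append([])
            return len(nodes) - 1

        def build(node: Node) -> int:
            i = add(node.label if node.is_leaf else None)
            for c in node.children:
                j = build(c)
                adj[i].append(j)
                adj[j].append(i)
            return i

        build(self.root)
        og = next(i for i, lab in enumerate(nodes) if lab == outgroup)

        def rebuild(i: int, parent: int) -> Node:
            nbrs = [j for j in adj[i] if j != parent]
            if not nbrs:
                return Node(label=nodes[i])
            if len(nbrs) == 1 and nodes[i] is None:
                # suppress degree-two internal node (old root)
                return rebuild(nbrs[0], i)
            return Node(children=[rebuild(j, i) for j in nbrs])

        ingroup = rebuild(adj[og][0], og)
        return PhyloTree(Node(children=[Node(label=outgroup), ingroup]))

    def copy(self) -> "PhyloTree":
        def cp(node: Node) -> Node:
            if node.is_leaf:
                return Node(label=node.label)
            return Node(children=[cp(c) for c in node.children])

        return PhyloTree(cp(self.root))


def build_tree_from_clades(taxa: Iterable, clades: Iterable) -> PhyloTree:
    """Assemble a (possibly multifurcating) rooted tree from nested clades.

    ``clades`` must be pairwise compatible (nested or disjoint); the full
    taxon set and singletons are implied and need not be listed.
    """
    taxa = sorted(set(taxa))
    full = frozenset(taxa)
    cl = {frozenset(c) for c in clades if 1 < len(frozenset(c)) < len(full)}
    for a in cl:
        for b in cl:
            if a & b and not (a <= b or b <= a):
                raise ContractError("incompatible clades cannot form a tree")
    ordered = sorted(cl, key=len, reverse=True)
    root = Node()
    holder: dict[frozenset, Node] = {full: root}
    parent_sets: dict[int, frozenset] = {id(root): full}

    def place(target: frozenset) -> None:
        # find smallest existing clade containing target
        best = min((s for s in holder if target < s), key=len)
        node = Node()
        # move children of holder[best] fully inside target under node
        kept, moved = [], []
        for ch in holder[best].children:
            s = _leafset(ch)
            (moved if s <= target else kept).append(ch)
        node.children = moved
        holder[best].children = kept + [node]
        holder[target] = node

    def _leafset(node: Node) -> frozenset:
        if node.is_leaf:
            return frozenset([node.label])
        return frozenset().union(*(_leafset(c) for c in node.children))

    for t in taxa:
        root.children.append(Node(label=t))
    for c in ordered:
        place(c)
    return PhyloTree(root)
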