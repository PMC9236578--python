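"""Reading, writing and manipulating phylogenetic trees.

Trees are held in a small node-based structure (:class:`Phylogeny`) that is
convenient for the topology-only work done in this package: restriction to
taxon subsets, canonical edge enumeration and rerooting.  Newick parsing is
delegated to :mod:`dendropy`; only writing is done natively.

Conventions
-----------
* A tree whose root has exactly two children is *rooted*; a root of degree
  three (or more) marks an *unrooted* tree.
* Edge identifiers are assigned by a deterministic canonicalization: the
  unrooted tree is (re)oriented away from its lexicographically smallest
  leaf, children are sorted by smallest descendant label, and edges are
  numbered 1..2n-3 in post-order.  The numbering therefore depends only on
  the labeled topology, never on the newick rotation it was read from.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Iterator

import dendropy

__all__ = [
    "Node",
    "Phylogeny",
    "TreeParseError",
    "TreeValidationError",
    "read_newick",
    "write_newick",
    "restrict",
    "canonical_edges",
    "reroot_on_edge",
    "unroot",
]


class TreeParseError(ValueError):
    """Raised when newick input cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates a structural precondition."""


class Node:
    """A tree node; leaves carry a label, all nodes may carry a length."""

    __slots__ = ("children", "label", "length")

    def __init__(self, children: list["Node"] | None = None,
                 label: str | None = None,
                 length: float | None = None):
        self.children: list[Node] = children if children is not None else []
        self.label = label
        self.length = length

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def copy(self) -> "Node":
        return Node([c.copy() for c in self.children], self.label, self.length)


class Phylogeny:
    """A leaf-labeled tree, rooted or unrooted, with optional branch lengths."""

    def __init__(self, root: Node, rooted: bool):
        self.root = root
        self.rooted = rooted
        labels = [leaf.label for leaf in self.leaves()]
        if any(l is None for l in labels):
            raise TreeValidationError("every leaf must carry a label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeValidationError(f"duplicate leaf labels: {dupes}")

    # -- traversal ---------------------------------------------------------

    def leaves(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                yield node
            else:
                stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        return tuple(sorted(leaf.label for leaf in self.leaves()))

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.leaves())

    def is_binary(self) -> bool:
        """True when every internal node is bifurcating (root may be
        trifurcating in the unrooted case)."""
        for node in self.postorder():
            if node.is_leaf:
                continue
            k = len(node.children)
            if node is self.root:
                want = 2 if self.rooted else 3
                if k != want:
                    return False
            elif k != 2:
                return False
        return True

    def copy(self) -> "Phylogeny":
        return Phylogeny(self.root.copy(), self.rooted)

    # -- set encodings -----------------------------------------------------

    def clades(self, nontrivial: bool = True) -> set[frozenset[str]]:
        """Clades (descendant leaf-label sets) of a rooted tree.

        With ``nontrivial=True`` (default), singletons and the full leaf set
        are excluded, so a binary rooted tree on n leaves yields n-2 clades.
        """
        if not self.rooted:
            raise TreeValidationError("clades are defined for rooted trees")
        return self._descendant_sets(nontrivial)

    def _descendant_sets(self, nontrivial: bool) -> set[frozenset[str]]:
        n = self.n_leaves
        out: set[frozenset[str]] = set()
        below: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.label])
            else:
                s = frozenset().union(*(below[id(c)] for c in node.children))
                below[id(node)] = s
                if node is not self.root:
                    if not nontrivial or 1 < len(s) < n:
                        out.add(s)
        return out

    def bipartitions(self) -> set[frozenset[str]]:
        """Nontrivial bipartitions of the unrooted topology.

        Each bipartition is encoded canonically as the side *not* containing
        the lexicographically smallest leaf label.
        """
        all_leaves = frozenset(self.leaf_labels)
        anchor = min(all_leaves)
        out: set[frozenset[str]] = set()
        for s in self._descendant_sets(nontrivial=False):
            side = all_leaves - s if anchor in s else s
            if 1 < len(side) < len(all_leaves) - 1:
                out.add(side)
        return out

    def to_newick(self, lengths: bool = True) -> str:
        return write_newick(self, lengths=lengths)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "rooted" if self.rooted else "unrooted"
        return f"<Phylogeny {kind} n={self.n_leaves} {self.to_newick()}>"


# -- newick I/O ------------------------------------------------------------


def _from_dendropy(dtree: dendropy.Tree) -> Phylogeny:
    def convert(dnode) -> Node:
        children = [convert(c) for c in dnode.child_nodes()]
        label = None
        if not children:
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        return Node(children, label, dnode.edge.length)

    root = convert(dtree.seed_node)
    if len(root.children) == 1:
        # suppress a degree-one root knuckle produced by some writers
        root = root.children[0]
        root.length = None
    rooted = len(root.children) == 2
    return Phylogeny(root, rooted)


def read_newick(source: str | os.PathLike) -> list[Phylogeny]:
    """Read one tree per line from a newick string or file path.

    The rooted flag is inferred from the degree of the root node: two
    children mean rooted, three or more mean unrooted.
    """
    if isinstance(source, os.PathLike):
        text = open(source).read()
    elif isinstance(source, str) and "(" not in source:
        text = open(source).read()
    else:
        text = source
    trees: list[Phylogeny] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        try:
            dtree = dendropy.Tree.get(
                data=line, schema="newick", preserve_underscores=True,
                suppress_internal_node_taxa=True)
        except Exception as exc:
            if "Duplicate taxon labels" in str(exc):
                raise TreeValidationError(
                    f"duplicate leaf labels on line {lineno}: {exc}") from exc
            raise TreeParseError(f"malformed newick on line {lineno}: {exc}") from exc
        try:
            trees.append(_from_dendropy(dtree))
        except TreeValidationError as exc:
            raise TreeValidationError(f"line {lineno}: {exc}") from exc
    return trees


def _needs_quotes(label: str) -> bool:
    special = set("()[]{}/\\,;:=*'\"`<>^ \t\n")
    return any(ch in special for ch in label)


def write_newick(tree: Phylogeny, lengths: bool = True) -> str:
    def fmt(node: Node) -> str:
        if node.is_leaf:
            s = f"'{node.label}'" if _needs_quotes(node.label) else node.label
        else:
            s = "(" + ",".join(fmt(c) for c in node.children) + ")"
        if lengths and node.length is not None:
            s += f":{node.length:g}"
        return s

    return fmt(tree.root) + ";"


# -- restriction -----------------------------------------------------------


def restrict(tree: Phylogeny, taxa: Iterable[str]) -> Phylogeny:
    """Induced subtree on ``taxa`` with degree-two nodes suppressed.

    Branch lengths, when present, are summed across suppressed nodes.  For a
    rooted input the induced tree is rooted at the MRCA of ``taxa``; for an
    unrooted input the result is unrooted.
    """
    taxa = frozenset(taxa)
    have = frozenset(tree.leaf_labels)
    missing = sorted(taxa - have)
    if missing:
        raise TreeValidationError(f"taxa not in tree: {missing}")
    if len(taxa) < 3:
        raise TreeValidationError("restriction needs at least 3 taxa")

    def prune(node: Node) -> Node | None:
        if node.is_leaf:
            if node.label in taxa:
                return Node([], node.label, node.length)
            return None
        kept = [k for k in (prune(c) for c in node.children) if k is not None]
        if not kept:
            return None
        if len(kept) == 1:
            child = kept[0]
            if child.length is not None and node.length is not None:
                child.length += node.length
            elif node.length is not None:
                child.length = node.length
            return child
        return Node(kept, None, node.length)

    root = prune(tree.root)
    assert root is not None
    root.length = None
    if tree.rooted:
        return Phylogeny(root, True)
    # unrooted: re-polytomize a degree-two root left by the pruning
    if len(root.children) == 2:
        left, right = root.children
        host, other = (left, right) if not left.is_leaf else (right, left)
        if host.is_leaf:  # only two taxa survive below; cannot happen (>=3)
            return Phylogeny(root, False)
        if other.length is not None and host.length is not None:
            other.length += host.length
        elif host.length is not None:
            other.length = host.length
        host_as_root = Node(host.children + [other], None, None)
        return Phylogeny(host_as_root, False)
    return Phylogeny(root, False)


# -- canonical edges and rerooting ----------------------------------------


@dataclass(frozen=True)
class Edge:
    """An edge of an unrooted tree in canonical orientation.

    ``clade`` is the leaf set on the far side of the edge from the canonical
    anchor leaf (the lexicographically smallest label).
    """

    edge_id: int
    clade: frozenset[str]
    length: float | None


def _adjacency(tree: Phylogeny):
    """Undirected adjacency over node objects, with edge lengths.

    For a rooted tree the degree-two root is suppressed so that the
    adjacency describes the unrooted topology.
    """
    adj: dict[int, list[tuple[Node, float | None]]] = {}
    obj: dict[int, Node] = {}

    def add(u: Node, v: Node, length: float | None):
        adj.setdefault(id(u), []).append((v, length))
        adj.setdefault(id(v), []).append((u, length))
        obj[id(u)] = u
        obj[id(v)] = v

    def walk(node: Node):
        for c in node.children:
            add(node, c, c.length)
            walk(c)

    root = tree.root
    if tree.rooted and len(root.children) == 2:
        a, b = root.children
        length = None
        if a.length is not None or b.length is not None:
            length = (a.length or 0.0) + (b.length or 0.0)
        add(a, b, length)
        for c in (a, b):
            for g in c.children:
                add(c, g, g.length)
                walk(g)
    else:
        walk(root)
    return adj, obj


def canonical_edges(tree: Phylogeny) -> list[Edge]:
    """Deterministic edge enumeration of the unrooted topology of ``tree``.

    Returns 2n-3 edges for a binary tree on n leaves, numbered 1..2n-3.
    """
    adj, _ = _adjacency(tree)
    leaves = {leaf.label: leaf for leaf in tree.leaves()}
    anchor = leaves[min(leaves)]

    min_label: dict[int, str] = {}
    below: dict[int, frozenset[str]] = {}

    def collect(node: Node, parent: Node | None) -> frozenset[str]:
        kids = [v for v, _ in adj[id(node)] if v is not parent]
        if not kids and node.is_leaf:
            s = frozenset([node.label])
        else:
            s = frozenset().union(*(collect(v, node) for v in kids))
            if node.is_leaf:  # anchor leaf acting as traversal root
                s = s | frozenset([node.label])
        below[id(node)] = s
        min_label[id(node)] = min(s)
        return s

    collect(anchor, None)

    edges: list[Edge] = []

    def emit(node: Node, parent: Node | None):
        kids = sorted(
            ((v, ln) for v, ln in adj[id(node)] if v is not parent),
            key=lambda pair: min_label[id(pair[0])])
        for v, ln in kids:
            emit(v, node)
            edges.append(Edge(len(edges) + 1, below[id(v)], ln))

    emit(anchor, None)
    return edges


def reroot_on_edge(tree: Phylogeny, edge_id: int) -> Phylogeny:
    """Root the unrooted ``tree`` by subdividing the canonical edge
    ``edge_id``; the unrooted topology of the result equals the input."""
    if tree.rooted:
        raise TreeValidationError("reroot_on_edge expects an unrooted tree")
    adj, _ = _adjacency(tree)
    edges = canonical_edges(tree)
    matching = [e for e in edges if e.edge_id == edge_id]
    if not matching:
        raise TreeValidationError(
            f"invalid edge id {edge_id}; tree has {len(edges)} edges")
    target = matching[0]

    # locate the two endpoint nodes of the target edge by matching the clade
    anchor_label = min(tree.leaf_labels)

    def find(node: Node, parent: Node | None) -> tuple[Node, Node, float | None] | None:
        for v, ln in adj[id(node)]:
            if v is parent:
                continue
            s = _side(v, node)
            if s == target.clade:
                return v, node, ln
            got = find(v, node)
            if got is not None:
                return got
        return None

    side_cache: dict[tuple[int, int], frozenset[str]] = {}

    def _side(node: Node, parent: Node) -> frozenset[str]:
        key = (id(node), id(parent))
        if key in side_cache:
            return side_cache[key]
        parts = [frozenset([node.label])] if node.is_leaf else []
        for v, _ in adj[id(node)]:
            if v is parent:
                continue
            parts.append(_side(v, node))
        s = frozenset().union(*parts)
        side_cache[key] = s
        return s

    anchor = next(leaf for leaf in tree.leaves() if leaf.label == anchor_label)
    found = find(anchor, None)
    assert found is not None
    child_node, parent_node, length = found

    def hang(node: Node, come_from: Node) -> Node:
        kids = [hang(v, node) for v, _ in adj[id(node)] if v is not come_from]
        length_in = next(ln for v, ln in adj[id(node)] if v is come_from)
        return Node(kids, node.label if node.is_leaf else None, length_in)

    half = None if length is None else length / 2.0
    left = hang(child_node, parent_node)
    right = hang(parent_node, child_node)
    left.length = half
    right.length = half
    return Phylogeny(Node([left, right], None, None), True)


def unroot(tree: Phylogeny) -> Phylogeny:
    """Forget the root: suppress a degree-two root into a trifurcation."""
    if not tree.rooted:
        return tree.copy()
    root = tree.root
    a, b = (c.copy() for c in root.children)
    host, other = (a, b) if not a.is_leaf else (b, a)
    if host.is_leaf:
        raise TreeValidationError("cannot unroot a two-leaf tree")
    if other.length is not None or host.length is not None:
        other.length = (other.length or 0.0) + (host.length or 0.0)
    new_root = Node(host.children + [other], None, None)
    return Phylogeny(new_root, False)
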