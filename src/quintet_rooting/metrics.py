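"""Evaluation metrics for rooted and unrooted trees.

The main rooting error is the normalized clade distance between two rooted
binary trees on the same n leaves:

    ( |Clades(T*) \\ Clades(T)| + |Clades(T) \\ Clades(T*)| ) / (2n - 4)

where Clades(.) is the set of nontrivial clades (singletons and the full
leaf set excluded; a rooted binary tree has n-2 of them).  When both trees
root the *same* unrooted topology t, the clade-distance numerator equals
twice the root distance, the number of edges of t separating the two root
edges.

Unrooted trees are compared by the normalized Robinson-Foulds bipartition
distance, which also underlies the two dataset-level summaries used in
simulation studies: GTEE (gene tree estimation error: distance between true
and estimated gene trees) and AD (average discordance: mean distance
between the species tree and the true gene trees, a measure of ILS).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .trees_io import Phylogeny, TreeValidationError, canonical_edges, restrict

__all__ = [
    "DistanceReport",
    "clade_distance",
    "root_distance",
    "rf_distance",
    "average_discordance",
    "proportion_correctly_rooted",
]


@dataclass(frozen=True)
class DistanceReport:
    """Clade-distance decomposition: ``normalized = numerator / denominator``
    with denominator 2n-4."""

    numerator: int
    denominator: int
    normalized: float


def _check_same_leaves(t1: Phylogeny, t2: Phylogeny) -> int:
    l1, l2 = t1.leaf_labels, t2.leaf_labels
    if l1 != l2:
        raise TreeValidationError(
            f"leaf sets differ: {sorted(set(l1) ^ set(l2))}")
    return len(l1)


def clade_distance(estimated: Phylogeny, true: Phylogeny) -> DistanceReport:
    """Normalized clade distance between two rooted trees on the same
    leaves (n >= 3)."""
    if not (estimated.rooted and true.rooted):
        raise TreeValidationError("clade_distance expects rooted trees")
    n = _check_same_leaves(estimated, true)
    if n < 3:
        raise TreeValidationError("clade_distance needs n >= 3")
    diff = len(estimated.clades() ^ true.clades())
    denom = 2 * n - 4
    return DistanceReport(diff, denom, diff / denom)


def root_distance(unrooted: Phylogeny, estimated: Phylogeny,
                  true: Phylogeny) -> int:
    """Number of edges of ``unrooted`` between the root edges of two of its
    rootings.  Satisfies: clade-distance numerator = 2 * root distance."""
    if unrooted.rooted:
        raise TreeValidationError("first argument must be the unrooted tree")
    e1 = _root_edge_id(unrooted, estimated)
    e2 = _root_edge_id(unrooted, true)
    if e1 == e2:
        return 0
    return _edge_path_length(unrooted, e1, e2)


def _root_edge_id(unrooted: Phylogeny, rooted: Phylogeny) -> int:
    """Canonical edge id of ``unrooted`` on which ``rooted`` places its root."""
    if not rooted.rooted:
        raise TreeValidationError("expected a rooted tree")
    _check_same_leaves(unrooted, rooted)
    if rooted.bipartitions() != unrooted.bipartitions():
        raise TreeValidationError(
            "the rooted tree is not a rooting of the unrooted topology")
    full = frozenset(rooted.leaf_labels)
    anchor = min(full)
    side = min((_leafset(c) for c in rooted.root.children),
               key=lambda s: len(s))
    # express the root bipartition on the same side as canonical edges
    # (the side away from the anchor leaf)
    side = side if anchor not in side else full - side
    for edge in canonical_edges(unrooted):
        if edge.clade == side:
            return edge.edge_id
    raise TreeValidationError(
        "the rooted tree is not a rooting of the unrooted topology")


def _leafset(node) -> frozenset:
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n.label)
        else:
            stack.extend(n.children)
    return frozenset(out)


def _edge_path_length(tree: Phylogeny, e1: int, e2: int) -> int:
    """Edges strictly between two edges of a tree, plus one: adjacent edges
    are at distance 1."""
    from .trees_io import _adjacency

    adj, _ = _adjacency(tree)
    # recover endpoints of canonical edges by matching the away-from-anchor
    # leaf sets during a traversal from the anchor leaf
    anchor_label = min(tree.leaf_labels)
    anchor = next(l for l in tree.leaves() if l.label == anchor_label)
    edges = {e.clade: e.edge_id for e in canonical_edges(tree)}

    # build parent structure and clades with an explicit stack
    parents = {id(anchor): None}
    order = [anchor]
    stack = [anchor]
    while stack:
        node = stack.pop()
        for v, _ in adj[id(node)]:
            if id(v) not in parents:
                parents[id(v)] = node
                order.append(v)
                stack.append(v)
    below: dict[int, frozenset] = {}
    for node in reversed(order):
        s = frozenset([node.label]) if node.is_leaf else frozenset()
        for v, _ in adj[id(node)]:
            if parents.get(id(v)) is node:
                s |= below[id(v)]
        below[id(node)] = s
    node_of_edge = {}
    for node in order:
        if parents[id(node)] is not None:
            eid = edges.get(below[id(node)])
            if eid is not None:
                node_of_edge[eid] = node
    # distance between edges e1, e2: each edge is (node, parent(node));
    # count edges on the path between the two edge midpoints
    def path_to_root(node):
        path = []
        while node is not None:
            path.append(id(node))
            node = parents[id(node)]
        return path

    n1, n2 = node_of_edge[e1], node_of_edge[e2]
    p1 = path_to_root(n1)
    p2 = path_to_root(n2)
    set1 = {nid: i for i, nid in enumerate(p1)}
    for j, nid in enumerate(p2):
        if nid in set1:
            i = set1[nid]
            # the node path between the lower endpoints has i + j edges;
            # it traverses e1 and e2 themselves only when the meeting node
            # lies strictly above them (i > 0 and j > 0)
            return i + j - 1 if (i > 0 and j > 0) else i + j
    raise AssertionError("edges lie in one tree; a common ancestor must exist")


def rf_distance(t1: Phylogeny, t2: Phylogeny) -> float:
    """Normalized Robinson-Foulds distance between two unrooted topologies:
    bipartition symmetric difference over the total bipartition count."""
    _check_same_leaves(t1, t2)
    b1, b2 = t1.bipartitions(), t2.bipartitions()
    if not b1 and not b2:
        return 0.0
    return len(b1 ^ b2) / (len(b1) + len(b2))


def average_discordance(species_tree: Phylogeny,
                        gene_trees: Iterable[Phylogeny]) -> float:
    """Mean normalized bipartition distance between the species tree and
    each gene tree (restricted to shared taxa); the standard measure of ILS
    level in simulation studies."""
    total = 0.0
    count = 0
    sp_taxa = frozenset(species_tree.leaf_labels)
    for gt in gene_trees:
        shared = sp_taxa & frozenset(gt.leaf_labels)
        if len(shared) < 4:
            continue
        sp = restrict(species_tree, shared) if shared != sp_taxa else species_tree
        gt_r = restrict(gt, shared) if shared != frozenset(gt.leaf_labels) else gt
        sp_u = sp
        if sp_u.rooted:
            from .trees_io import unroot
            sp_u = unroot(sp_u)
        total += rf_distance(sp_u, gt_r)
        count += 1
    if count == 0:
        raise TreeValidationError("no gene tree shares >= 4 taxa with the "
                                  "species tree")
    return total / count


def proportion_correctly_rooted(pairs: Sequence[tuple[Phylogeny, Phylogeny]]
                                ) -> float:
    """Fraction of (estimated, true) rooted pairs with clade distance 0."""
    if not pairs:
        raise ValueError("need at least one pair")
    hits = sum(1 for est, true in pairs
               if clade_distance(est, true).numerator == 0)
    return hits / len(pairs)
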