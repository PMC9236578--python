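"""Enumeration and canonical indexing of five-taxon (quintet) topologies.

An unrooted binary tree on the ordered leaf tuple (a, b, c, d, e) is
identified by its two *cherry pairs*: every such tree has exactly two
nontrivial bipartitions, each separating a pair of leaves from the other
three, and the unordered pair of disjoint 2-subsets determines the topology.
There are C(5,2)*C(3,2)/2 = 15 of them.  Rooting any one of the 15 on any of
its 7 edges gives the 105 labeled rooted quintet topologies, each of which
falls into one of three shape categories: caterpillar, balanced or
pseudo-caterpillar.

Canonical orders
----------------
* Unrooted index 1..15: topologies sorted lexicographically by their sorted
  cherry-pair encoding over leaf positions 0..4.
* Rooted id 1..105: ``(unrooted_index - 1) * 7 + edge_id`` where edge ids
  1..7 come from :func:`quintet_rooting.trees_io.canonical_edges`.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations

from .trees_io import (Node, Phylogeny, TreeValidationError, canonical_edges,
                       reroot_on_edge)

__all__ = [
    "LEAVES",
    "CATERPILLAR",
    "BALANCED",
    "PSEUDO_CATERPILLAR",
    "SHAPES",
    "RootedQuintet",
    "enumerate_unrooted_quintets",
    "enumerate_rooted_quintets",
    "quintet_tree",
    "rooted_quintet_tree",
    "topology_index",
    "rooted_id_from_clades",
    "classify_shape",
    "apply_permutation",
    "apply_permutation_rooted",
    "unrooted_pairsets",
]

LEAVES: tuple[str, ...] = ("a", "b", "c", "d", "e")

CATERPILLAR = "caterpillar"
BALANCED = "balanced"
PSEUDO_CATERPILLAR = "pseudo-caterpillar"
SHAPES = (CATERPILLAR, BALANCED, PSEUDO_CATERPILLAR)

Pair = frozenset  # a 2-subset of leaf positions {0..4}
PairSet = frozenset  # a frozenset of two disjoint Pairs


def _pairset_key(ps: PairSet) -> tuple:
    return tuple(sorted(tuple(sorted(p)) for p in ps))


@lru_cache(maxsize=1)
def unrooted_pairsets() -> tuple[PairSet, ...]:
    """The 15 unrooted quintet topologies as cherry-pair sets, in canonical
    (lexicographic) order."""
    out = set()
    for p in combinations(range(5), 2):
        rest = [x for x in range(5) if x not in p]
        for q in combinations(rest, 2):
            out.add(frozenset({frozenset(p), frozenset(q)}))
    return tuple(sorted(out, key=_pairset_key))


@lru_cache(maxsize=1)
def _pairset_index() -> dict[PairSet, int]:
    return {ps: i + 1 for i, ps in enumerate(unrooted_pairsets())}


def quintet_tree(index: int) -> Phylogeny:
    """Unrooted tree (labels a..e) for canonical unrooted index 1..15."""
    ps = unrooted_pairsets()[index - 1]
    pair_a, pair_b = sorted(ps, key=lambda p: tuple(sorted(p)))
    (middle,) = set(range(5)) - pair_a - pair_b

    def cherry(pair: Pair) -> Node:
        i, j = sorted(pair)
        return Node([Node(label=LEAVES[i]), Node(label=LEAVES[j])])

    root = Node([cherry(pair_a), cherry(pair_b), Node(label=LEAVES[middle])])
    return Phylogeny(root, rooted=False)


def enumerate_unrooted_quintets() -> list[Phylogeny]:
    """All 15 unrooted binary quintet topologies, canonical order."""
    return [quintet_tree(i) for i in range(1, 16)]


def topology_index(tree: Phylogeny,
                   leaf_order: tuple[str, ...] | None = None) -> int:
    """Canonical index (1..15) of an unrooted binary quintet topology.

    ``leaf_order`` maps the tree's taxa onto positions (a, b, c, d, e); by
    default the taxa are sorted lexicographically.
    """
    labels = tree.leaf_labels
    if len(labels) != 5:
        raise TreeValidationError(f"expected 5 leaves, found {len(labels)}")
    order = tuple(leaf_order) if leaf_order is not None else labels
    if sorted(order) != sorted(labels):
        raise TreeValidationError("leaf_order must be a permutation of the taxa")
    pos = {lab: i for i, lab in enumerate(order)}
    pairs = set()
    full = frozenset(labels)
    for side in tree.bipartitions():
        small = side if len(side) == 2 else full - side
        pairs.add(frozenset(pos[x] for x in small))
    if len(pairs) != 2:
        raise TreeValidationError("unresolved (non-binary) quintet")
    return _pairset_index()[frozenset(pairs)]


# -- rooted quintets -------------------------------------------------------


@dataclass(frozen=True)
class RootedQuintet:
    """One of the 105 labeled rooted binary quintet topologies."""

    id: int                        # 1..105
    unrooted_index: int            # 1..15
    edge_id: int                   # 1..7, canonical edge of the unrooted tree
    shape: str                     # one of SHAPES
    clades: frozenset[frozenset[int]]  # the 3 nontrivial clades, leaf positions


def _clade_positions(tree: Phylogeny) -> frozenset[frozenset[int]]:
    pos = {lab: i for i, lab in enumerate(LEAVES)}
    return frozenset(frozenset(pos[x] for x in c) for c in tree.clades())


def classify_shape(tree: Phylogeny) -> str:
    """Shape category of a rooted binary 5-leaf tree.

    The root of a caterpillar splits 1|4 with the 4-subtree again fully
    unbalanced; a balanced tree splits 2|3; a pseudo-caterpillar splits 1|4
    with the 4-subtree splitting 2|2.  Equivalently the clade-size multiset
    is {2,3,4}, {2,2,3} or {2,2,4}.
    """
    if not tree.rooted:
        raise TreeValidationError("shape is defined for rooted trees")
    if tree.n_leaves != 5 or not tree.is_binary():
        raise TreeValidationError("shape needs a binary 5-leaf rooted tree")
    sizes = tuple(sorted(len(c) for c in tree.clades()))
    return {(2, 3, 4): CATERPILLAR,
            (2, 2, 3): BALANCED,
            (2, 2, 4): PSEUDO_CATERPILLAR}[sizes]


@lru_cache(maxsize=1)
def enumerate_rooted_quintets() -> tuple[RootedQuintet, ...]:
    """All 105 rooted quintet topologies: 15 unrooted trees x 7 root edges."""
    out: list[RootedQuintet] = []
    seen: set[frozenset[frozenset[int]]] = set()
    for u_idx in range(1, 16):
        utree = quintet_tree(u_idx)
        n_edges = len(canonical_edges(utree))
        assert n_edges == 7
        for edge_id in range(1, 8):
            rtree = reroot_on_edge(utree, edge_id)
            clades = _clade_positions(rtree)
            assert clades not in seen, "duplicate rooted topology"
            seen.add(clades)
            out.append(RootedQuintet(
                id=(u_idx - 1) * 7 + edge_id,
                unrooted_index=u_idx,
                edge_id=edge_id,
                shape=classify_shape(rtree),
                clades=clades))
    return tuple(out)


@lru_cache(maxsize=1)
def _rooted_index() -> dict[frozenset[frozenset[int]], int]:
    return {rq.clades: rq.id for rq in enumerate_rooted_quintets()}


def rooted_id_from_clades(clades: frozenset[frozenset[int]]) -> int:
    """Rooted quintet id (1..105) from its nontrivial clade set."""
    return _rooted_index()[clades]


def rooted_quintet_tree(rq_id: int) -> Phylogeny:
    """Rooted tree (labels a..e) for rooted quintet id 1..105."""
    rq = enumerate_rooted_quintets()[rq_id - 1]
    return reroot_on_edge(quintet_tree(rq.unrooted_index), rq.edge_id)


# -- permutation action ----------------------------------------------------


def apply_permutation(index: int, perm: tuple[int, ...]) -> int:
    """Image of an unrooted topology index under a leaf relabeling.

    ``perm[i]`` is the new position of the leaf currently at position i.
    The map is a group action: identity and composition laws hold.
    """
    ps = unrooted_pairsets()[index - 1]
    moved = frozenset(frozenset(perm[x] for x in pair) for pair in ps)
    return _pairset_index()[moved]


def apply_permutation_rooted(rq_id: int, perm: tuple[int, ...]) -> int:
    """Image of a rooted quintet id under a leaf relabeling."""
    rq = enumerate_rooted_quintets()[rq_id - 1]
    moved = frozenset(frozenset(perm[x] for x in c) for c in rq.clades)
    return _rooted_index()[moved]


@lru_cache(maxsize=1)
def all_permutations() -> tuple[tuple[int, ...], ...]:
    return tuple(permutations(range(5)))
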