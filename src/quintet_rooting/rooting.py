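"""The Quintet Rooting search: choose a root edge for an unrooted species
tree by scoring candidate rootings against quintet gene-tree frequencies.

For a five-taxon tree the method is exact search: tally the empirical
distribution u-hat over the 15 unrooted quintet topologies once, score each
of the 7 rootings with the chosen cost, and return the argmin.

For n > 5 taxa, each of the 2n-3 candidate rootings R is scored as

    Score(R, T) = sum_{q in Q*} Cost(R|_q, u-hat_q)

where Q* is a collection of five-taxon subsets, u-hat_q the empirical
quintet distribution for subset q, and R|_q the rooted quintet that R
induces on q.  Two modes are provided:

* ``all``    -- Q* is every C(n, 5) subset; O(k n^5) tally work.
* ``linear`` -- Q* has O(n) subsets chosen from the unrooted topology (one
  per internal edge, spanning its four subtrees plus the nearest fifth
  lineage); O(k n) tally work.  Faster, uses less information.

Costs are computed once per subset for all 105 rooted quintet topologies
and cached; candidates then only look up the cost of their induced quintet,
which exploits the fact that the 2n-3 candidates induce at most 7 distinct
rootings on any subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .cost import EmptyQuintetSupportError, QuintetDistribution, all_rooted_costs
from .quintets import rooted_id_from_clades, unrooted_pairsets
from .trees_io import Phylogeny, TreeValidationError, canonical_edges, reroot_on_edge

__all__ = [
    "RootingResult",
    "root_quintet",
    "root_tree",
    "TIE_TOLERANCE",
]

log = logging.getLogger(__name__)

TIE_TOLERANCE = 1e-12
MODES = ("all", "linear")


@dataclass(frozen=True)
class RootingResult:
    """Outcome of a rooting search.

    ``candidates`` holds (canonical root-edge id, score) for all 2n-3
    rootings in edge-id order; ``tie`` is set when at least two scores are
    within 1e-12 of the minimum (the lowest edge id is then selected).
    """

    mode: str
    variant: int
    candidates: tuple[tuple[int, float], ...]
    selected_edge: int
    selected_tree: Phylogeny
    tie: bool
    n_quintets: int
    n_skipped_quintets: int

    @property
    def selected_score(self) -> float:
        by_id = dict(self.candidates)
        return by_id[self.selected_edge]


def root_quintet(tree: Phylogeny, gene_trees: Sequence[Phylogeny],
                 variant: int = 4, experimental: bool = False) -> RootingResult:
    """Root an unrooted five-taxon tree by exhaustive scoring of its 7
    rootings against the empirical quintet distribution."""
    if len(tree.leaf_labels) != 5:
        raise TreeValidationError("root_quintet expects exactly 5 taxa")
    return root_tree(tree, gene_trees, mode="all", variant=variant,
                     experimental=experimental)


def root_tree(tree: Phylogeny, gene_trees: Sequence[Phylogeny],
              mode: str = "all", variant: int = 4,
              experimental: bool = False,
              linear_strategy: str = "edge-spanning") -> RootingResult:
    """Root an unrooted n-taxon species tree (n >= 5) from unrooted gene
    trees; see the module docstring for the two modes.

    ``linear_strategy`` names the O(n) subset construction used by
    ``mode="linear"``; "edge-spanning" (one quintet per internal edge) is
    the only scheme currently shipped, and the flag exists so alternative
    constructions can be added without changing the interface.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {MODES}")
    if linear_strategy != "edge-spanning":
        raise ValueError(f"unknown linear strategy {linear_strategy!r}")
    if tree.rooted:
        raise TreeValidationError("the input species tree must be unrooted")
    if not tree.is_binary():
        raise TreeValidationError("the input species tree must be binary")
    taxa = tree.leaf_labels
    n = len(taxa)
    if n < 5:
        raise TreeValidationError("rooting needs at least 5 taxa")
    pos = {lab: i for i, lab in enumerate(taxa)}
    full = (1 << n) - 1

    tally = _GeneTreeTally(gene_trees, pos)
    edges = canonical_edges(tree)
    cand_clades = _candidate_clades(edges, pos, full)

    if mode == "all":
        subsets = [frozenset(c) for c in combinations(range(n), 5)]
    else:
        subsets = _linear_subsets(tree, pos)

    scores = np.zeros(len(edges))
    used = 0
    skipped = 0
    for q in subsets:
        s_mask = 0
        for i in q:
            s_mask |= 1 << i
        dist = tally.distribution(s_mask)
        if dist is None:
            skipped += 1
            log.info("quintet %s has no gene-tree support; skipped",
                     sorted(taxa[i] for i in q))
            continue
        used += 1
        costs = all_rooted_costs(dist, variant, experimental)
        local = _local_positions(s_mask)
        cache: dict[frozenset, float] = {}
        for e_idx, clades in enumerate(cand_clades):
            induced = frozenset(c & s_mask for c in clades
                                if 2 <= (c & s_mask).bit_count() <= 4)
            got = cache.get(induced)
            if got is None:
                key = frozenset(frozenset(local[b] for b in _bits(c))
                                for c in induced)
                got = float(costs[rooted_id_from_clades(key) - 1])
                cache[induced] = got
            scores[e_idx] += got

    if used == 0:
        raise EmptyQuintetSupportError(
            "no five-taxon subset has any gene-tree support")

    best = float(scores.min())
    tied = [edges[i].edge_id for i in range(len(edges))
            if scores[i] <= best + TIE_TOLERANCE]
    selected = min(tied)
    if len(tied) > 1:
        log.info("rooting tie between edges %s; selecting edge %d",
                 tied, selected)
    return RootingResult(
        mode=mode,
        variant=variant,
        candidates=tuple((edges[i].edge_id, float(scores[i]))
                         for i in range(len(edges))),
        selected_edge=selected,
        selected_tree=reroot_on_edge(tree, selected),
        tie=len(tied) > 1,
        n_quintets=used,
        n_skipped_quintets=skipped)


# -- gene-tree tallying ----------------------------------------------------


def _bits(mask: int):
    while mask:
        b = mask & -mask
        yield b
        mask ^= b


def _local_positions(s_mask: int) -> dict[int, int]:
    """Map single-bit masks within the subset to positions 0..4 (taxa in
    ascending label order map to the reference leaves a..e)."""
    return {b: i for i, b in enumerate(_bits(s_mask))}


class _GeneTreeTally:
    """Vectorized quintet-topology tallying over a fixed set of gene trees.

    Every internal edge of every gene tree is encoded once as the bitmask
    (over the species taxa) of the leaves below it; restricting to a
    five-taxon subset S and reading off the two cherry bipartitions is then
    pure integer arithmetic.
    """

    def __init__(self, gene_trees: Iterable[Phylogeny], pos: dict[str, int]):
        clade_masks: list[int] = []
        clade_tree: list[int] = []
        leaf_masks: list[int] = []
        for t_idx, tree in enumerate(gene_trees):
            lm = 0
            below: dict[int, int] = {}
            for node in tree.postorder():
                if node.is_leaf:
                    p = pos.get(node.label)
                    below[id(node)] = 0 if p is None else 1 << p
                else:
                    below[id(node)] = 0
                    for c in node.children:
                        below[id(node)] |= below[id(c)]
                if node is tree.root:
                    lm = below[id(node)]
                elif not node.is_leaf and below[id(node)]:
                    clade_masks.append(below[id(node)])
                    clade_tree.append(t_idx)
            leaf_masks.append(lm)
        self.n_trees = len(leaf_masks)
        self.clades = np.asarray(clade_masks, dtype=np.int64)
        self.clade_tree = np.asarray(clade_tree, dtype=np.int64)
        self.leaf_masks = np.asarray(leaf_masks, dtype=np.int64)
        idx = {ps: i for i, ps in enumerate(unrooted_pairsets())}
        self._pairset_idx = idx

    def distribution(self, s_mask: int) -> QuintetDistribution | None:
        """Empirical quintet distribution for the 5-taxon subset ``s_mask``;
        None when no gene tree carries all five taxa (or none is resolved)."""
        qualified = (self.leaf_masks & s_mask) == s_mask
        if not qualified.any():
            return None
        sel = qualified[self.clade_tree]
        x = (self.clades & s_mask)[sel]
        genes = self.clade_tree[sel]
        pc = np.bitwise_count(x)
        keep = (pc == 2) | (pc == 3)
        pairs = np.where(pc[keep] == 2, x[keep], s_mask ^ x[keep])
        genes = genes[keep]
        key = (genes << 33) | pairs
        uniq = np.unique(key)
        ug = uniq >> 33
        up = uniq & ((1 << 33) - 1)
        # genes contributing exactly two distinct cherry bipartitions are
        # resolved quintets; fewer means the restriction had a polytomy
        first = np.r_[True, ug[1:] != ug[:-1]]
        starts = np.flatnonzero(first)
        counts = np.diff(np.r_[starts, len(ug)])
        two = counts == 2
        if not two.any():
            return None
        i0 = starts[two]
        local = _local_positions(int(s_mask))
        pair_local = {}
        for b1, p1 in local.items():
            for b2, p2 in local.items():
                if b1 < b2:
                    pair_local[b1 | b2] = frozenset((p1, p2))
        tallies = np.zeros(15)
        for a, b in zip(up[i0], up[i0 + 1]):
            ps = frozenset((pair_local[int(a)], pair_local[int(b)]))
            tallies[self._pairset_idx[ps]] += 1
        support = int(tallies.sum())
        n_dropped = int(qualified.sum()) - support
        if n_dropped:
            log.info("dropped %d unresolved quintet restrictions", n_dropped)
        if support == 0:
            return None
        return QuintetDistribution(tallies / support, support)


# -- candidate rootings ----------------------------------------------------


def _candidate_clades(edges, pos: dict[str, int], full: int) -> list[list[int]]:
    """For each candidate root edge, the clade bitmasks of the rooted tree
    obtained by subdividing that edge."""
    masks = []
    for e in edges:
        m = 0
        for lab in e.clade:
            m |= 1 << pos[lab]
        masks.append(m)
    out: list[list[int]] = []
    for i, be in enumerate(masks):
        clades = [be, full ^ be]
        for j, bf in enumerate(masks):
            if j == i:
                continue
            if (bf & be) == be and bf != be:  # edge j is above the new root
                clades.append(full ^ bf)
            else:
                clades.append(bf)
        out.append(clades)
    return out


# -- linear-encoding subset selection -------------------------------------


def _linear_subsets(tree: Phylogeny, pos: dict[str, int]) -> list[frozenset]:
    """One quintet per internal edge of the unrooted topology: one nearest
    leaf from each of the four subtrees hanging off the edge, plus the
    nearest remaining leaf (ties broken lexicographically).  Yields at most
    n-3 distinct subsets whose union of induced rootings covers every
    candidate edge's neighborhood."""
    from .trees_io import _adjacency

    adj, obj = _adjacency(tree)

    def neighbors(node):
        return [v for v, _ in adj[id(node)]]

    def bfs_leaves(start, blocked):
        """(distance, label) pairs of leaves reachable from ``start``
        without stepping onto ``blocked``."""
        seen = {id(start), id(blocked)}
        frontier = [(start, 0)]
        found = []
        while frontier:
            node, d = frontier.pop(0)
            if node.is_leaf:
                found.append((d, node.label))
            for v in neighbors(node):
                if id(v) not in seen:
                    seen.add(id(v))
                    frontier.append((v, d + 1))
        return found

    # internal edges: unordered pairs of adjacent internal nodes
    internal_edges = []
    seen_pairs = set()
    for key, nbrs in adj.items():
        u = obj[key]
        if u.is_leaf:
            continue
        for w, _ in nbrs:
            if w.is_leaf:
                continue
            pid = frozenset((id(u), id(w)))
            if pid not in seen_pairs:
                seen_pairs.add(pid)
                internal_edges.append((u, w))

    def edge_key(e):
        u, w = e
        return tuple(sorted((min(l for _, l in bfs_leaves(u, w)),
                             min(l for _, l in bfs_leaves(w, u)))))

    subsets: list[frozenset] = []
    seen_subsets: set[frozenset] = set()
    for u, w in sorted(internal_edges, key=edge_key):
        chosen: list[str] = []
        for a, b in ((u, w), (w, u)):
            for v in neighbors(a):
                if v is not b:
                    _, lab = min(bfs_leaves(v, a))
                    chosen.append(lab)
        if len(chosen) < 5:  # fifth lineage: nearest leaf not already chosen
            remaining: dict[str, int] = {}
            for d, lab in bfs_leaves(u, w) + bfs_leaves(w, u):
                if lab not in chosen and d < remaining.get(lab, 10 ** 9):
                    remaining[lab] = d
            _, lab = min((d, lab) for lab, d in remaining.items())
            chosen.append(lab)
        subset = frozenset(pos[lab] for lab in chosen)
        if subset not in seen_subsets:
            seen_subsets.add(subset)
            subsets.append(subset)
    return subsets
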