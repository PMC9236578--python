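"""Equivalence classes and inequalities of quintet gene-tree probabilities.

Under the multi-species coalescent, the vector (u_1, ..., u_15) of unrooted
quintet gene-tree topology probabilities generated by a rooted five-taxon
species tree satisfies a system of linear *invariants* (equalities) and
strict *inequalities* that depends only on the shape of the rooted tree —
caterpillar, balanced or pseudo-caterpillar — and not on its branch lengths
(Allman-Degnan-Rhodes, ADR).  The invariants partition {u_1..u_15} into
equivalence classes; the inequalities impose a partial order between
classes.  These structures identify the rooted topology: the true rooted
tree is the only one of the 105 whose constraints the true distribution
satisfies exactly.

This module stores the three base structures (one per shape, on the
reference labelings below) as explicit data and generates the remaining 102
by leaf permutation.  Everything downstream (the cost functions, the
rooting search) consumes these tables.

u-index convention
------------------
ADR index the 15 unrooted topologies u_1..u_15.  The correspondence with
cherry pairs used here (leaves a..e = positions 0..4):

    u1 ={ab,de}  u2 ={ab,ce}  u3 ={ab,cd}  u4 ={ac,de}  u5 ={ac,be}
    u6 ={ac,bd}  u7 ={ad,ce}  u8 ={ad,be}  u9 ={ad,bc}  u10={bd,ce}
    u11={ae,bd}  u12={ae,bc}  u13={bc,de}  u14={ae,cd}  u15={be,cd}

This assignment is pinned by three kinds of constraints: u1 is the unrooted
topology of all three reference trees; within-column symmetry groups of the
reference trees force the pair memberships ({u4,u13}, {u6,u9}, {u5,u12},
{u8,u11}); and the inequality directions fix the rest.  Indices that the
structures never separate ({u7,u10,u14,u15}, and the order within pairs)
are assigned lexicographically.  The transcription is checksummed by the
published penalty-term counts (18/23/31 invariant terms, 28/44/54
inequality terms, weighted 19/20/19) and validated in the test suite by an
exact coalescent computation of the quintet distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from .quintets import (BALANCED, CATERPILLAR, PSEUDO_CATERPILLAR,
                       apply_permutation, all_permutations,
                       enumerate_rooted_quintets, unrooted_pairsets)

__all__ = [
    "AdrStructure",
    "PenaltyCounts",
    "U_PAIRSETS",
    "U_TO_CANONICAL",
    "CANONICAL_TO_U",
    "REFERENCE_ROOTED_ID",
    "base_structure",
    "structure_for",
    "all_structures",
    "count_penalty_terms",
    "export_table",
]

# -- the ADR u-indexing, as cherry pairs over leaf positions 0..4 ----------

_U = {
    1: ((0, 1), (3, 4)),   2: ((0, 1), (2, 4)),   3: ((0, 1), (2, 3)),
    4: ((0, 2), (3, 4)),   5: ((0, 2), (1, 4)),   6: ((0, 2), (1, 3)),
    7: ((0, 3), (2, 4)),   8: ((0, 3), (1, 4)),   9: ((0, 3), (1, 2)),
    10: ((1, 3), (2, 4)),  11: ((0, 4), (1, 3)),  12: ((0, 4), (1, 2)),
    13: ((1, 2), (3, 4)),  14: ((0, 4), (2, 3)),  15: ((1, 4), (2, 3)),
}

U_PAIRSETS = {u: frozenset({frozenset(p), frozenset(q)})
              for u, (p, q) in _U.items()}

# -- the three base structures, in u-indices -------------------------------
#
# Reference trees:   caterpillar        ((((a,b),c),d),e)
#                    balanced           (((a,b),c),(d,e))
#                    pseudo-caterpillar (((a,b),(d,e)),c)
#
# "order" lists covering relations between classes (by class position):
# (i, j) means every u in classes[i] strictly exceeds every u in classes[j]
# for all positive branch lengths.

_BASE_U = {
    CATERPILLAR: {
        "classes": [{1}, {2}, {3}, {4, 13}, {6, 9}, {5, 12},
                    {7, 8, 10, 11, 14, 15}],
        "order": [(0, 1), (0, 3), (2, 1), (2, 4), (1, 5), (3, 5), (4, 5),
                  (5, 6)],
    },
    BALANCED: {
        "classes": [{1}, {2, 3}, {4, 13}, {5, 6, 9, 12},
                    {7, 8, 10, 11, 14, 15}],
        "order": [(0, 1), (0, 2), (1, 3), (2, 3), (3, 4)],
    },
    PSEUDO_CATERPILLAR: {
        "classes": [{1}, {2, 3}, {4, 13}, {8, 11},
                    {5, 6, 7, 9, 10, 12, 14, 15}],
        "order": [(0, 1), (0, 2), (0, 3), (1, 4), (2, 4), (3, 4)],
    },
}

_REF_CLADES = {
    CATERPILLAR: frozenset({frozenset({0, 1}), frozenset({0, 1, 2}),
                            frozenset({0, 1, 2, 3})}),
    BALANCED: frozenset({frozenset({0, 1}), frozenset({0, 1, 2}),
                         frozenset({3, 4})}),
    PSEUDO_CATERPILLAR: frozenset({frozenset({0, 1}), frozenset({3, 4}),
                                   frozenset({0, 1, 3, 4})}),
}


@lru_cache(maxsize=1)
def _u_to_canonical() -> dict[int, int]:
    idx = {ps: i + 1 for i, ps in enumerate(unrooted_pairsets())}
    return {u: idx[ps] for u, ps in U_PAIRSETS.items()}


def __getattr__(name):  # computed constants, derived once from the data
    if name == "U_TO_CANONICAL":
        return dict(_u_to_canonical())
    if name == "CANONICAL_TO_U":
        return {c: u for u, c in _u_to_canonical().items()}
    if name == "REFERENCE_ROOTED_ID":
        return dict(_reference_ids())
    raise AttributeError(name)


@lru_cache(maxsize=1)
def _reference_ids() -> dict[str, int]:
    by_clades = {rq.clades: rq.id for rq in enumerate_rooted_quintets()}
    return {shape: by_clades[clades] for shape, clades in _REF_CLADES.items()}


@dataclass(frozen=True)
class AdrStructure:
    """Equivalence classes and inequality partial order for one rooted
    quintet topology.

    ``classes`` partition the canonical unrooted indices {1..15};
    ``order`` holds (i, j) class positions meaning classes[i] > classes[j]
    elementwise.
    """

    owner: int  # rooted quintet id, 1..105
    classes: tuple[frozenset[int], ...]
    order: tuple[tuple[int, int], ...]

    def signature(self) -> tuple:
        """Canonical, owner-independent encoding used to compare structures."""
        keyed = sorted(range(len(self.classes)),
                       key=lambda i: tuple(sorted(self.classes[i])))
        rank = {old: new for new, old in enumerate(keyed)}
        classes = tuple(tuple(sorted(self.classes[i])) for i in keyed)
        order = tuple(sorted((rank[i], rank[j]) for i, j in self.order))
        return (classes, order)


def _structure_from_u(shape: str, owner: int) -> AdrStructure:
    conv = _u_to_canonical()
    spec = _BASE_U[shape]
    classes = tuple(frozenset(conv[u] for u in cls) for cls in spec["classes"])
    return AdrStructure(owner=owner, classes=classes,
                        order=tuple(spec["order"]))


def base_structure(shape: str) -> AdrStructure:
    """The published structure for a shape's reference labeling, expressed
    over canonical topology indices."""
    return _structure_from_u(shape, _reference_ids()[shape])


@lru_cache(maxsize=1)
def all_structures() -> tuple[AdrStructure, ...]:
    """Structures for all 105 rooted quintets, generated from the base
    structures by leaf permutation."""
    rooted = enumerate_rooted_quintets()
    out: list[AdrStructure] = []
    for rq in rooted:
        ref_clades = _REF_CLADES[rq.shape]
        sigma = None
        for perm in all_permutations():
            if frozenset(frozenset(perm[x] for x in c)
                         for c in ref_clades) == rq.clades:
                sigma = perm
                break
        assert sigma is not None
        base = base_structure(rq.shape)
        classes = tuple(frozenset(apply_permutation(i, sigma) for i in cls)
                        for cls in base.classes)
        out.append(AdrStructure(owner=rq.id, classes=classes,
                                order=base.order))
    return tuple(out)


def structure_for(rq_id: int) -> AdrStructure:
    """ADR structure of rooted quintet id 1..105."""
    if not 1 <= rq_id <= 105:
        raise ValueError(f"rooted quintet id out of range: {rq_id}")
    return all_structures()[rq_id - 1]


@dataclass(frozen=True)
class PenaltyCounts:
    """Census of the penalty terms a structure contributes to the cost.

    ``invariant_terms``    -- unordered within-class pairs, sum C(|c|, 2)
    ``inequality_terms``   -- cross-class pairs, sum |c|*|c'| over c > c'
    ``weighted_invariant`` -- independent within-class constraints,
                              sum (|c| - 1)
    ``weighted_inequality``-- inequality terms after 1/|c'| scaling, sum |c|
    """

    invariant_terms: int
    inequality_terms: int
    weighted_invariant: int
    weighted_inequality: int

    @property
    def total(self) -> int:
        return self.invariant_terms + self.inequality_terms

    @property
    def weighted_total(self) -> int:
        return self.weighted_invariant + self.weighted_inequality


def count_penalty_terms(structure: AdrStructure) -> PenaltyCounts:
    sizes = [len(c) for c in structure.classes]
    inv = sum(s * (s - 1) // 2 for s in sizes)
    ineq = sum(sizes[i] * sizes[j] for i, j in structure.order)
    w_inv = sum(s - 1 for s in sizes)
    w_ineq = sum(sizes[i] for i, _ in structure.order)
    return PenaltyCounts(inv, ineq, w_inv, w_ineq)


def validate_structure(structure: AdrStructure) -> None:
    """Check partition and acyclicity invariants; raise on violation."""
    seen: set[int] = set()
    for cls in structure.classes:
        if seen & cls:
            raise ValueError("classes overlap")
        seen |= cls
    if seen != set(range(1, 16)):
        raise ValueError("classes do not partition 1..15")
    # acyclicity of the order's transitive closure by DFS
    adj: dict[int, list[int]] = {}
    for i, j in structure.order:
        if i == j:
            raise ValueError("order is not irreflexive")
        adj.setdefault(i, []).append(j)
    state: dict[int, int] = {}

    def dfs(v: int) -> None:
        state[v] = 1
        for w in adj.get(v, ()):
            if state.get(w) == 1:
                raise ValueError("order has a cycle")
            if state.get(w) is None:
                dfs(w)
        state[v] = 2

    for v in list(adj):
        if state.get(v) is None:
            dfs(v)


def export_table() -> str:
    """Plain-text dump of all 105 structures.

    One record per line::

        id <tab> shape <tab> classes <tab> order

    where ``classes`` joins sorted index blocks with ``|`` (for example
    ``1|2,3|...``) and ``order`` lists covering relations ``i>j`` between
    class positions, comma separated.
    """
    rooted = enumerate_rooted_quintets()
    lines = ["# rooted-quintet ADR structures; topology indices are the"
             " canonical 1..15 order",
             "# id\tshape\tclasses\torder"]
    for rq, st in zip(rooted, all_structures()):
        classes = "|".join(",".join(str(i) for i in sorted(c))
                           for c in st.classes)
        order = ",".join(f"{i}>{j}" for i, j in st.order)
        lines.append(f"{rq.id}\t{rq.shape}\t{classes}\t{order}")
    return "\n".join(lines) + "\n"
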