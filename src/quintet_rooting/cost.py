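"""Scoring rooted quintet topologies against quintet frequency vectors.

The production cost (variant 4) measures how far an estimated distribution
u-hat over the 15 unrooted quintet topologies is from satisfying the
invariants and inequalities of a candidate rooted quintet R:

    Cost(R, u) =   sum_{c in C_R} (1/|c|)  sum_{a<b in c}      |u_a - u_b|
                 + sum_{c > c'}   (1/|c'|) sum_{a in c, b in c'} max(0, u_b - u_a)

The 1/|c| and 1/|c'| factors correct a category bias: without them the raw
number of penalty terms differs strongly between shapes (46 caterpillar, 67
balanced, 85 pseudo-caterpillar) and the search systematically favors
caterpillar rootings.  Ablation variants are kept for comparison:

* variant 1 -- invariants only (normalized);
* variant 2 -- invariants + inequalities, all weights 1;
* variant 3 -- alternative inequality normalization; the published scheme is
  not reproduced here, so this variant is experimental and opt-in: the
  stand-in divides inequality terms by the size of the *larger* class.
* variant 4 -- the production cost above.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable

import numpy as np

from . import adr_tables
from .trees_io import Phylogeny, TreeValidationError, restrict
from .quintets import topology_index

__all__ = [
    "QuintetDistribution",
    "EmptyQuintetSupportError",
    "empirical_distribution",
    "cost",
    "cost4",
    "cost_variant",
    "all_rooted_costs",
    "VARIANTS",
]

log = logging.getLogger(__name__)

VARIANTS = (1, 2, 3, 4)
_SUM_TOL = 1e-9


class EmptyQuintetSupportError(ValueError):
    """No gene tree informs the requested five-taxon subset."""


@dataclass(frozen=True)
class QuintetDistribution:
    """Relative frequencies of the 15 unrooted quintet topologies.

    ``freqs[i]`` is the frequency of canonical topology index i+1;
    ``support`` counts the gene trees that were tallied.
    """

    freqs: np.ndarray
    support: int

    def __post_init__(self):
        freqs = np.asarray(self.freqs, dtype=float)
        object.__setattr__(self, "freqs", freqs)
        if freqs.shape != (15,):
            raise ValueError("expected 15 topology frequencies")
        if np.any(freqs < 0):
            raise ValueError("frequencies must be nonnegative")
        if self.support > 0 and abs(freqs.sum() - 1.0) > _SUM_TOL:
            raise ValueError("frequencies must sum to 1")
        if self.support == 0 and freqs.any():
            raise ValueError("zero support requires an all-zero vector")


def empirical_distribution(gene_trees: Iterable[Phylogeny],
                           taxa: Iterable[str]) -> QuintetDistribution:
    """Tally the unrooted topologies of gene trees restricted to ``taxa``.

    Gene trees missing any of the five taxa are excluded from numerator and
    denominator alike; restrictions that are unresolved (non-binary) are
    dropped and logged.  Rooted gene trees are used via their unrooted
    topology.
    """
    taxa = frozenset(taxa)
    if len(taxa) != 5:
        raise ValueError("a quintet needs exactly 5 taxa")
    counts = np.zeros(15)
    skipped_nonbinary = 0
    for tree in gene_trees:
        if not taxa <= frozenset(tree.leaf_labels):
            continue
        sub = restrict(tree, taxa)
        try:
            idx = topology_index(sub)
        except TreeValidationError:
            skipped_nonbinary += 1
            continue
        counts[idx - 1] += 1
    if skipped_nonbinary:
        log.info("dropped %d unresolved quintet restrictions for taxa %s",
                 skipped_nonbinary, sorted(taxa))
    support = int(counts.sum())
    if support == 0:
        raise EmptyQuintetSupportError(
            f"no gene tree contains all of {sorted(taxa)}")
    return QuintetDistribution(counts / support, support)


# -- vectorized penalty-term tables ---------------------------------------


@lru_cache(maxsize=None)
def _term_tables(variant: int):
    """Per-variant penalty terms for all 105 rooted quintets, padded into
    rectangular arrays for vectorized evaluation.

    Returns (inv_a, inv_b, inv_w, ineq_a, ineq_b, ineq_w); `a`/`b` hold
    0-based topology indices, padding rows carry weight 0.
    """
    inv_terms: list[list[tuple[int, int, float]]] = []
    ineq_terms: list[list[tuple[int, int, float]]] = []
    for st in adr_tables.all_structures():
        inv: list[tuple[int, int, float]] = []
        for cls in st.classes:
            w = 1.0 if variant == 2 else 1.0 / len(cls)
            members = sorted(cls)
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    inv.append((a - 1, b - 1, w))
        ineq: list[tuple[int, int, float]] = []
        if variant != 1:
            for ci, cj in st.order:
                upper, lower = st.classes[ci], st.classes[cj]
                if variant == 2:
                    w = 1.0
                elif variant == 3:
                    w = 1.0 / max(len(upper), len(lower))
                else:
                    w = 1.0 / len(lower)
                for a in sorted(upper):
                    for b in sorted(lower):
                        ineq.append((a - 1, b - 1, w))
        inv_terms.append(inv)
        ineq_terms.append(ineq)

    def pad(rows):
        width = max(len(r) for r in rows)
        a = np.zeros((len(rows), width), dtype=np.intp)
        b = np.zeros((len(rows), width), dtype=np.intp)
        w = np.zeros((len(rows), width))
        for i, row in enumerate(rows):
            for j, (ai, bi, wi) in enumerate(row):
                a[i, j], b[i, j], w[i, j] = ai, bi, wi
        return a, b, w

    if all(not r for r in ineq_terms):
        ineq_terms = [[(0, 0, 0.0)] for _ in ineq_terms]
    return pad(inv_terms) + pad(ineq_terms)


def _as_freqs(u) -> np.ndarray:
    if isinstance(u, QuintetDistribution):
        return u.freqs
    freqs = np.asarray(u, dtype=float)
    if freqs.shape != (15,):
        raise ValueError("expected a 15-vector of topology frequencies")
    if np.any(freqs < 0) or abs(freqs.sum() - 1.0) > _SUM_TOL:
        raise ValueError("cost expects a normalized frequency vector; "
                         "normalize explicitly before scoring")
    return freqs


def _check_variant(variant: int, experimental: bool) -> None:
    if variant not in VARIANTS:
        raise ValueError(f"unknown cost variant {variant}; choose from {VARIANTS}")
    if variant == 3 and not experimental:
        raise NotImplementedError(
            "cost variant 3 uses a stand-in normalization; pass "
            "experimental=True to use it anyway")


def all_rooted_costs(u, variant: int = 4,
                     experimental: bool = False) -> np.ndarray:
    """Costs of all 105 rooted quintet topologies against ``u`` (15-vector
    or QuintetDistribution), as an array indexed by rooted id - 1."""
    _check_variant(variant, experimental)
    freqs = _as_freqs(u)
    ia, ib, iw, qa, qb, qw = _term_tables(variant)
    inv = np.abs(freqs[ia] - freqs[ib])
    ineq = np.maximum(0.0, freqs[qb] - freqs[qa])
    return (iw * inv).sum(axis=1) + (qw * ineq).sum(axis=1)


def cost(rq_id: int, u, variant: int = 4, experimental: bool = False) -> float:
    """Cost of rooted quintet ``rq_id`` (1..105) against distribution ``u``."""
    if not 1 <= rq_id <= 105:
        raise ValueError(f"rooted quintet id out of range: {rq_id}")
    return float(all_rooted_costs(u, variant, experimental)[rq_id - 1])


def cost4(rq_id: int, u) -> float:
    """The production (normalized invariants + inequalities) cost."""
    return cost(rq_id, u, variant=4)


def cost_variant(variant: int, rq_id: int, u,
                 experimental: bool = False) -> float:
    """Ablation costs: 1 = invariants only, 2 = unnormalized, 3 =
    experimental alternative normalization."""
    return cost(rq_id, u, variant=variant, experimental=experimental)
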