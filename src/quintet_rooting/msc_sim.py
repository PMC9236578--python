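"""Gene-tree simulation under the multi-species coalescent (MSC).

Gene trees are generated inside a rooted model species tree whose branch
lengths are in coalescent units (CU).  One lineage enters at each leaf;
within a species-tree branch of duration t, the m extant lineages coalesce
in pairs at rate 1 per pair (waiting times Exp(C(m, 2))), and lineages that
reach the root keep coalescing until one remains.  Returned gene trees are
unrooted, with branch lengths in CU.

Terminal branch lengths are irrelevant to the topology distribution when a
single allele is sampled per species (no coalescence is possible there);
unspecified terminal lengths default to 1 CU so that output trees always
carry lengths.

Two perturbation helpers emulate features of real data at desk scale:
random lognormal branch-length rescaling (deviation from a molecular
clock), and random NNI moves (a controllable analogue of gene tree
estimation error).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .trees_io import Node, Phylogeny, TreeValidationError, unroot

__all__ = [
    "simulate_gene_trees",
    "perturb_clock",
    "nni_perturb",
]


def _prepare_model(model: Phylogeny):
    """Validate the model tree and compute node ages.

    Ages increase root-ward: age(root) = 0, age(child) = age(parent) - L.
    Returns (postorder list of (node, age), root age offset irrelevant).
    """
    if not model.rooted:
        raise TreeValidationError("the model species tree must be rooted")
    if not model.is_binary():
        raise TreeValidationError("the model species tree must be binary")
    ages: dict[int, float] = {id(model.root): 0.0}
    order: list[tuple[Node, float]] = []
    stack = [model.root]
    while stack:
        node = stack.pop()
        age = ages[id(node)]
        order.append((node, age))
        for child in node.children:
            length = child.length
            if length is None:
                if child.is_leaf:
                    length = 1.0  # default terminal length, 1 CU
                else:
                    raise TreeValidationError(
                        "internal branches of the model tree need lengths")
            if length <= 0:
                raise TreeValidationError(
                    "model branch lengths must be positive")
            ages[id(child)] = age - length
            stack.append(child)
    order.reverse()  # children before parents
    return order, ages


class _GeneNode:
    __slots__ = ("children", "label", "age")

    def __init__(self, children, label, age):
        self.children = children
        self.label = label
        self.age = age


def _to_phylogeny(root: _GeneNode, lengths: bool) -> Phylogeny:
    def convert(g: _GeneNode, parent_age: float | None) -> Node:
        length = None
        if lengths and parent_age is not None:
            length = parent_age - g.age
        return Node([convert(c, g.age) for c in g.children], g.label, length)

    return unroot(Phylogeny(convert(root, None), rooted=True))


def simulate_gene_trees(model: Phylogeny, k: int,
                        seed: int | np.random.SeedSequence,
                        lengths: bool = True) -> list[Phylogeny]:
    """Simulate ``k`` unrooted gene trees under the MSC within ``model``.

    A single seeded generator drives the run, with an independent child
    stream spawned per gene, so results are reproducible and insensitive to
    the order in which genes are consumed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    order, ages = _prepare_model(model)
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    streams = ss.spawn(k)
    out: list[Phylogeny] = []
    for g in range(k):
        rng = np.random.default_rng(streams[g])
        out.append(_simulate_one(order, ages, rng, lengths))
    return out


def _simulate_one(order, ages, rng, lengths) -> Phylogeny:
    pool: dict[int, list[_GeneNode]] = {}
    root_entry = order[-1]
    for node, age in order:
        if node.is_leaf:
            lineages = [_GeneNode([], node.label, age)]
        else:
            lineages = []
            for child in node.children:
                lineages.extend(pool.pop(id(child)))
        is_root = node is root_entry[0]
        top = math.inf if is_root else ages[id(node)] + _branch_len(node)
        t = age
        m = len(lineages)
        while m > 1:
            rate = m * (m - 1) / 2.0
            t += rng.exponential(1.0 / rate)
            if t > top:
                break
            i, j = _pick_pair(rng, m)
            merged = _GeneNode([lineages[i], lineages[j]], None, t)
            lineages[i] = merged
            lineages[j] = lineages[m - 1]
            lineages.pop()
            m -= 1
        pool[id(node)] = lineages
    (root_lineage,) = pool[id(root_entry[0])]
    return _to_phylogeny(root_lineage, lengths)


def _branch_len(node: Node) -> float:
    if node.length is not None:
        return node.length
    return 1.0  # terminal default; validated in _prepare_model


def _pick_pair(rng, m: int) -> tuple[int, int]:
    i = int(rng.integers(m))
    j = int(rng.integers(m - 1))
    if j >= i:
        j += 1
    return (i, j) if i < j else (j, i)


def perturb_clock(gene_trees: Sequence[Phylogeny], sigma: float,
                  seed: int) -> list[Phylogeny]:
    """Multiply every branch length by an i.i.d. lognormal factor with log
    standard deviation ``sigma`` (mean factor e^{sigma^2/2}); topologies are
    untouched.  ``sigma=0`` is the identity."""
    rng = np.random.default_rng(seed)
    out = []
    for tree in gene_trees:
        new = tree.copy()
        if sigma > 0:
            for node in new.postorder():
                if node.length is not None:
                    node.length *= float(rng.lognormal(0.0, sigma))
        out.append(new)
    return out


def nni_perturb(gene_trees: Sequence[Phylogeny], prob: float,
                seed: int) -> list[Phylogeny]:
    """Apply one random NNI move to each tree independently with
    probability ``prob``; a controllable stand-in for gene tree estimation
    error in simulation studies."""
    if not 0 <= prob <= 1:
        raise ValueError("prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for tree in gene_trees:
        new = tree.copy()
        if rng.random() < prob:
            _random_nni(new, rng)
        out.append(new)
    return out


def _random_nni(tree: Phylogeny, rng) -> None:
    # internal edges: (parent u, child v) with v internal
    edges = []
    stack = [tree.root]
    while stack:
        node = stack.pop()
        for child in node.children:
            if not child.is_leaf:
                edges.append((node, child))
            stack.append(child)
    if not edges:
        return
    u, v = edges[int(rng.integers(len(edges)))]
    others = [c for c in u.children if c is not v]
    w = others[int(rng.integers(len(others)))]
    x = v.children[int(rng.integers(len(v.children)))]
    ui = u.children.index(w)
    vi = v.children.index(x)
    u.children[ui], v.children[vi] = x, w
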