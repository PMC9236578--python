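"""Exact quintet gene-tree topology distributions under the MSC.

Independent oracle: enumerates coalescent histories branch by branch.
Within a branch of duration t starting with m lineages, the probability of
any *specific ordered sequence* of i pair-merges completing within t is
g(m, m-i, t) * prod 1/C(m_j, 2), where g is the lineage-count transition
function of the pure-death coalescent chain (computed by matrix exponential).
"""
from functools import lru_cache
import numpy as np
from scipy.linalg import expm


@lru_cache(maxsize=None)
def g_probs(m: int, t: float) -> tuple:
    """P(m lineages -> n lineages in time t) for n = m..1."""
    if t == float("inf"):
        return tuple(1.0 if n == 1 else 0.0 for n in range(m, 0, -1))
    # states m, m-1, ..., 1 ; rate j(j-1)/2 out of state j
    size = m
    Q = np.zeros((size, size))
    for k, j in enumerate(range(m, 0, -1)):
        lam = j * (j - 1) / 2.0
        Q[k, k] = -lam
        if k + 1 < size:
            Q[k + 1, k] = lam
    P = expm(Q * t)
    return tuple(P[:, 0])  # start in state m


def merge(a, b):
    return tuple(sorted((a, b), key=repr))


def ordered_sequences(lineages: tuple, i: int):
    """Yield (resulting multiset, pair-choice probability) over all ordered
    sequences of i merges starting from the given lineages."""
    if i == 0:
        yield tuple(sorted(lineages, key=repr)), 1.0
        return
    m = len(lineages)
    npairs = m * (m - 1) / 2.0
    for a in range(m):
        for b in range(a + 1, m):
            rest = [lineages[k] for k in range(m) if k not in (a, b)]
            rest.append(merge(lineages[a], lineages[b]))
            for res, p in ordered_sequences(tuple(rest), i - 1):
                yield res, p / npairs


def coalesce_branch(dist: dict, t: float) -> dict:
    out: dict = {}
    for state, p in dist.items():
        m = len(state)
        gp = g_probs(m, t)
        for i in range(m):  # i merges, ending with m - i lineages
            gm = gp[i]
            if gm <= 0:
                continue
            for res, cp in ordered_sequences(state, i):
                out[res] = out.get(res, 0.0) + p * gm * cp
    return out


def lineage_dist(node) -> dict:
    """Distribution over lineage multisets at the *top* of node's branch."""
    if node.is_leaf:
        dist = {((node.label,),): 1.0}
    else:
        parts = [lineage_dist(c) for c in node.children]
        dist = parts[0]
        for other in parts[1:]:
            combined = {}
            for s1, p1 in dist.items():
                for s2, p2 in other.items():
                    key = tuple(sorted(s1 + s2, key=repr))
                    combined[key] = combined.get(key, 0.0) + p1 * p2
            dist = combined
    t = node.length if node.length is not None else 0.0
    if len(next(iter(dist))) == 1:
        return dist
    return coalesce_branch(dist, t)


def leafset(lineage) -> frozenset:
    if len(lineage) == 1 and isinstance(lineage[0], str):
        return frozenset(lineage)
    return leafset(lineage[0]) | leafset(lineage[1])


def clades(lineage, acc):
    s = leafset(lineage)
    if len(s) > 1:
        acc.append(s)
        clades(lineage[0], acc)
        clades(lineage[1], acc)
    return acc


def exact_quintet_distribution(species_tree) -> np.ndarray:
    """Exact 15-vector of unrooted quintet topology probabilities (canonical
    order) for a rooted 5-taxon species tree with coalescent-unit lengths."""
    from quintet_rooting.quintets import unrooted_pairsets, LEAVES

    root = species_tree.root
    # force complete coalescence above the root
    dist_children = []
    for c in root.children:
        dist_children.append(lineage_dist(c))
    dist = dist_children[0]
    for other in dist_children[1:]:
        combined = {}
        for s1, p1 in dist.items():
            for s2, p2 in other.items():
                key = tuple(sorted(s1 + s2, key=repr))
                combined[key] = combined.get(key, 0.0) + p1 * p2
        dist = combined
    dist = coalesce_branch(dist, float("inf"))

    pos = {lab: i for i, lab in enumerate(LEAVES)}
    idx = {ps: i for i, ps in enumerate(unrooted_pairsets())}
    out = np.zeros(15)
    for state, p in dist.items():
        (tree,) = state
        cl = clades(tree, [])
        pairs = set()
        for s in cl:
            if len(s) == 2:
                pairs.add(frozenset(pos[x] for x in s))
            elif len(s) == 3:
                pairs.add(frozenset(pos[x] for x in set(LEAVES) - s))
        assert len(pairs) == 2, (tree, pairs)
        out[idx[frozenset(pairs)]] += p
    assert abs(out.sum() - 1.0) < 1e-9, out.sum()
    return out
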