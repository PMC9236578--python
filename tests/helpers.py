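"""Shared builders and independent oracles for the test suite."""
from __future__ import annotations

import numpy as np

from quintet_rooting.adr_tables import structure_for
from quintet_rooting.quintets import rooted_quintet_tree
from quintet_rooting.trees_io import Node, Phylogeny


def brute_force_cost(rq_id: int, u, variant: int = 4) -> float:
    """Independent oracle: literal term-by-term expansion of the
    invariants + inequalities penalties."""
    s = structure_for(rq_id)
    total = 0.0
    for cls in s.classes:
        members = sorted(cls)
        w = 1.0 if variant == 2 else 1.0 / len(cls)
        for x in range(len(members)):
            for y in range(x + 1, len(members)):
                total += w * abs(u[members[x] - 1] - u[members[y] - 1])
    if variant != 1:
        for ci, cj in s.order:
            w = 1.0 if variant == 2 else 1.0 / len(s.classes[cj])
            for a in s.classes[ci]:
                for b in s.classes[cj]:
                    total += w * max(0.0, u[b - 1] - u[a - 1])
    return total


def compatible_distribution(rq_id: int) -> np.ndarray:
    """A distribution satisfying rq_id's invariants exactly and all its
    inequalities strictly: class value decreases with depth in the order
    DAG."""
    s = structure_for(rq_id)
    depth = [0] * len(s.classes)
    for _ in range(len(s.classes)):
        for i, j in s.order:
            depth[j] = max(depth[j], depth[i] + 1)
    u = np.zeros(15)
    for ci, cls in enumerate(s.classes):
        for i in cls:
            u[i - 1] = 2.0 ** (-depth[ci])
    return u / u.sum()


def quintet_model(rq_id: int, lengths, terminal: float = 1.0) -> Phylogeny:
    """Rooted quintet species tree ``rq_id`` with the three internal branch
    lengths assigned deterministically (internal nodes ordered by their
    sorted leaf sets) and terminal branches at ``terminal`` CU."""
    tree = rooted_quintet_tree(rq_id)
    internals = []
    for node in tree.postorder():
        if node.is_leaf:
            node.length = terminal
        elif node is not tree.root:
            internals.append(node)

    def leafset(node):
        out, stack = [], [node]
        while stack:
            x = stack.pop()
            if x.is_leaf:
                out.append(x.label)
            else:
                stack.extend(x.children)
        return tuple(sorted(out))

    internals.sort(key=leafset)
    for node, L in zip(internals, lengths):
        node.length = float(L)
    return tree


def random_rooted_model(labels, rng: np.random.Generator,
                        internal_low: float, internal_high: float,
                        terminal: float = 1.0) -> Phylogeny:
    """Random rooted binary model tree: topology by uniform sequential
    joining, internal branch lengths ~ U(low, high) CU."""
    nodes = [Node(label=lab, length=terminal) for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = Node([nodes[i], nodes[j]],
                      length=float(rng.uniform(internal_low, internal_high)))
        nodes[i] = merged
        nodes.pop(j)
    nodes[0].length = None
    return Phylogeny(nodes[0], rooted=True)
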