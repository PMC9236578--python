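"""Invariant/inequality structures: transcription checks, permutation
equivariance, and validation against exact and simulated coalescent
distributions."""
import itertools

import numpy as np
import pytest
from scipy.stats import norm

from quintet_rooting.adr_tables import (base_structure,
                                        count_penalty_terms, structure_for,
                                        all_structures, validate_structure,
                                        export_table)
from quintet_rooting import adr_tables
from quintet_rooting.quintets import (BALANCED, CATERPILLAR,
                                      PSEUDO_CATERPILLAR, SHAPES,
                                      apply_permutation,
                                      apply_permutation_rooted,
                                      enumerate_rooted_quintets)
from quintet_rooting.cost import empirical_distribution
from quintet_rooting.msc_sim import simulate_gene_trees

from helpers import quintet_model
from _exact_msc import exact_quintet_distribution

U2C = None


def u2c(u):
    global U2C
    if U2C is None:
        U2C = adr_tables.U_TO_CANONICAL
    return U2C[u]


def test_caterpillar_base_classes_match_published_partition():
    st = base_structure(CATERPILLAR)
    want = [{1}, {2}, {3}, {4, 13}, {6, 9}, {5, 12},
            {7, 8, 10, 11, 14, 15}]
    got = {frozenset(cls) for cls in st.classes}
    assert got == {frozenset(u2c(u) for u in cls) for cls in want}


@pytest.mark.parametrize("shape,sizes", [
    (CATERPILLAR, (1, 1, 1, 2, 2, 2, 6)),
    (BALANCED, (1, 2, 2, 4, 6)),
    (PSEUDO_CATERPILLAR, (1, 2, 2, 2, 8)),
])
def test_class_size_multisets(shape, sizes):
    st = base_structure(shape)
    assert tuple(sorted(len(c) for c in st.classes)) == sizes


def test_all_structures_partition_and_acyclic():
    for st in all_structures():
        validate_structure(st)


def test_class_size_multiset_matches_shape_for_all_105():
    rooted = enumerate_rooted_quintets()
    for rq, st in zip(rooted, all_structures()):
        assert tuple(sorted(len(c) for c in st.classes)) == \
            tuple(sorted(len(c) for c in base_structure(rq.shape).classes))


def test_permutation_equivariance_of_structures():
    rng = np.random.default_rng(0)
    perms = [tuple(rng.permutation(5)) for _ in range(12)]
    for rq_id in (1, 16, 18, 19, 40, 77, 105):
        st = structure_for(rq_id)
        for p in perms:
            moved_id = apply_permutation_rooted(rq_id, p)
            moved_st = structure_for(moved_id)
            pushed = tuple(frozenset(apply_permutation(i, p) for i in cls)
                           for cls in st.classes)
            assert {frozenset(c) for c in pushed} == \
                {frozenset(c) for c in moved_st.classes}
            # the order must be carried along with the classes
            key = {frozenset(c): i for i, c in enumerate(moved_st.classes)}
            got = {(key[frozenset(pushed[i])], key[frozenset(pushed[j])])
                   for i, j in st.order}
            assert got == set(moved_st.order)


def test_export_table_has_105_records():
    lines = [l for l in export_table().splitlines() if not l.startswith("#")]
    assert len(lines) == 105
    assert lines[0].split("\t")[1] in SHAPES


def test_exact_distribution_satisfies_structures():
    """Exact coalescent quintet distributions obey every within-class
    equality and every order relation, for all three shapes, across a range
    of branch lengths."""
    from quintet_rooting.adr_tables import REFERENCE_ROOTED_ID
    for shape, rq_id in REFERENCE_ROOTED_ID.items():
        st = base_structure(shape)
        for lens in [(0.5, 0.5, 0.5), (0.1, 1.0, 2.0), (2.0, 0.2, 0.7)]:
            u = exact_quintet_distribution(quintet_model(rq_id, lens))
            for cls in st.classes:
                vals = [u[i - 1] for i in cls]
                assert max(vals) - min(vals) < 1e-12
            means = [np.mean([u[i - 1] for i in cls]) for cls in st.classes]
            for i, j in st.order:
                assert means[i] > means[j]


def test_simulated_frequencies_respect_structures():
    """Monte-Carlo validation: large simulated samples reproduce the
    within-class equalities (pooled two-proportion z-test, alpha = 1e-4,
    Bonferroni-corrected) and strictly respect every order relation."""
    from quintet_rooting.adr_tables import REFERENCE_ROOTED_ID
    k = 100_000
    n_comparisons = 18 + 23 + 31
    z_crit = norm.isf(1e-4 / 2 / n_comparisons)
    for shape, rq_id in REFERENCE_ROOTED_ID.items():
        model = quintet_model(rq_id, (0.5, 0.5, 0.5))
        gts = simulate_gene_trees(model, k, seed=1000 + rq_id, lengths=False)
        u = empirical_distribution(gts, set("abcde")).freqs
        st = base_structure(shape)
        for cls in st.classes:
            for a, b in itertools.combinations(sorted(cls), 2):
                p1, p2 = u[a - 1], u[b - 1]
                pbar = (p1 + p2) / 2
                z = abs(p1 - p2) / np.sqrt(2 * pbar * (1 - pbar) / k)
                assert z < z_crit, (shape, a, b, z)
        means = [np.mean([u[i - 1] for i in cls]) for cls in st.classes]
        for i, j in st.order:
            assert means[i] > means[j], (shape, i, j)


@pytest.mark.parametrize("shape,inv,ineq,w_total", [
    (CATERPILLAR, 18, 28, 19),
    (BALANCED, 23, 44, 20),
    (PSEUDO_CATERPILLAR, 31, 54, 19),
])
def test_penalty_counts_match_published_values(shape, inv, ineq, w_total):
    pc = count_penalty_terms(base_structure(shape))
    assert (pc.invariant_terms, pc.inequality_terms) == (inv, ineq)
    assert pc.total == inv + ineq
    assert pc.weighted_total == w_total
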