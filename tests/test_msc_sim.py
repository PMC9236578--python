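"""MSC simulator: determinism, agreement with the exact coalescent
distribution, limiting regimes, perturbations, and the identifiability of
the simulating rooted tree from its quintet distribution."""
import numpy as np
import pytest
from scipy.stats import chisquare

from quintet_rooting.adr_tables import REFERENCE_ROOTED_ID
from quintet_rooting.cost import all_rooted_costs, empirical_distribution
from quintet_rooting.msc_sim import (nni_perturb, perturb_clock,
                                     simulate_gene_trees)
from quintet_rooting.metrics import rf_distance
from quintet_rooting.quintets import topology_index
from quintet_rooting.rooting import root_quintet
from quintet_rooting.trees_io import TreeValidationError, read_newick, unroot

from helpers import quintet_model
from _exact_msc import exact_quintet_distribution


def test_same_seed_reproduces_output_exactly():
    model = quintet_model(18, (0.5, 0.5, 0.5))
    a = simulate_gene_trees(model, 50, seed=9)
    b = simulate_gene_trees(model, 50, seed=9)
    assert [t.to_newick() for t in a] == [t.to_newick() for t in b]
    c = simulate_gene_trees(model, 50, seed=10)
    assert [t.to_newick() for t in a] != [t.to_newick() for t in c]


def test_invalid_model_lengths_rejected():
    bad = read_newick("((((a:1,b:1):0,c:1):0.5,d:1):0.5,e:1);")[0]
    with pytest.raises(TreeValidationError, match="positive"):
        simulate_gene_trees(bad, 5, seed=0)
    missing = read_newick("((((a,b),c):0.5,d):0.5,e);")[0]
    with pytest.raises(TreeValidationError, match="lengths"):
        simulate_gene_trees(missing, 5, seed=0)


def test_long_branches_suppress_discordance():
    """With internal branches >= 10 CU nearly every gene tree matches the
    species topology (coalescence within each branch is near-certain)."""
    model = quintet_model(18, (10.0, 10.0, 10.0))
    gts = simulate_gene_trees(model, 1000, seed=4, lengths=False)
    sp = unroot(model)
    match = sum(1 for g in gts if rf_distance(sp, g) == 0.0)
    assert match / len(gts) >= 0.99


def test_simulated_frequencies_match_exact_distribution():
    """Chi-square goodness of fit of simulated topology counts against the
    exact coalescent distribution at generic branch lengths."""
    model = quintet_model(18, (0.4, 0.6, 0.8))
    probs = exact_quintet_distribution(model)
    k = 50_000
    gts = simulate_gene_trees(model, k, seed=12, lengths=False)
    counts = np.zeros(15)
    for g in gts:
        counts[topology_index(g) - 1] += 1
    stat, pvalue = chisquare(counts, probs * k)
    assert pvalue > 1e-4


def test_clock_perturbation_changes_lengths_not_topology():
    model = quintet_model(19, (0.5, 0.5, 0.5))
    gts = simulate_gene_trees(model, 100, seed=6)
    same = perturb_clock(gts, sigma=0.0, seed=1)
    assert [t.to_newick() for t in same] == [t.to_newick() for t in gts]
    moved = perturb_clock(gts, sigma=0.6, seed=1)
    for a, b in zip(gts, moved):
        assert a.bipartitions() == b.bipartitions()
    ratios = []
    for a, b in zip(gts, moved):
        for na, nb in zip(a.postorder(), b.postorder()):
            if na.length:
                ratios.append(nb.length / na.length)
    assert np.mean(ratios) == pytest.approx(np.exp(0.6 ** 2 / 2), rel=0.1)


def test_rooting_is_invariant_under_clock_perturbation():
    model = quintet_model(18, (0.5, 0.5, 0.5))
    gts = simulate_gene_trees(model, 2000, seed=8)
    res1 = root_quintet(unroot(model), gts)
    res2 = root_quintet(unroot(model), perturb_clock(gts, 1.0, seed=2))
    assert res1.candidates == res2.candidates


def test_nni_perturbation_rate_and_leafset():
    model = quintet_model(18, (1.0, 1.0, 1.0))
    gts = simulate_gene_trees(model, 400, seed=13, lengths=False)
    untouched = nni_perturb(gts, prob=0.0, seed=3)
    assert [t.to_newick() for t in untouched] == [t.to_newick() for t in gts]
    noisy = nni_perturb(gts, prob=1.0, seed=3)
    changed = 0
    for a, b in zip(gts, noisy):
        assert a.leaf_labels == b.leaf_labels
        if a.bipartitions() != b.bipartitions():
            changed += 1
    assert changed / len(gts) > 0.9  # an NNI move alters the topology


def test_exact_distribution_identifies_the_rooted_tree():
    """At the exact quintet distribution the simulating tree has cost 0 and
    attains the minimum; competitors outside the weak-constraint boundary
    are strictly separated."""
    for shape, rq_id in REFERENCE_ROOTED_ID.items():
        u = exact_quintet_distribution(quintet_model(rq_id, (0.5, 0.5, 0.5)))
        costs = all_rooted_costs(u, 4)
        assert costs[rq_id - 1] == pytest.approx(0.0, abs=1e-12)
        assert costs.min() == pytest.approx(0.0, abs=1e-12)


def test_empirical_recovery_for_caterpillar_and_pseudo():
    """Sampled recovery of the simulating rooted tree from 3x10^4 gene
    trees for the two shapes whose distributions sit strictly inside their
    constraint cones (the balanced shape lies on a boundary shared with two
    caterpillar rootings and is exercised separately)."""
    for shape in ("caterpillar", "pseudo-caterpillar"):
        rq_id = REFERENCE_ROOTED_ID[shape]
        model = quintet_model(rq_id, (0.5, 0.5, 0.5))
        gts = simulate_gene_trees(model, 30_000, seed=14, lengths=False)
        res = root_quintet(unroot(model), gts)
        got = res.selected_tree.clades()
        assert got == model.clades(), shape


def test_balanced_truth_is_on_the_zero_cost_boundary():
    """For a balanced quintet the true distribution also satisfies the
    adjacent caterpillar rootings' (weak) constraints; the truth must still
    score within the sampling-noise floor of the best candidate."""
    rq_id = REFERENCE_ROOTED_ID["balanced"]
    model = quintet_model(rq_id, (0.5, 0.5, 0.5))
    gts = simulate_gene_trees(model, 30_000, seed=15, lengths=False)
    u = empirical_distribution(gts, set("abcde"))
    costs = all_rooted_costs(u, 4)
    base = (rq_id - 1) // 7 * 7
    cand = costs[base:base + 7]
    truth_cost = costs[rq_id - 1]
    assert truth_cost < 0.02  # noise floor, not a structural violation
    assert sorted(cand).index(truth_cost) <= 2
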