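# Methods

## Model and assumptions

Gene trees are assumed to evolve inside a rooted binary species tree under
the multi-species coalescent (MSC): one lineage enters at each leaf (one
allele per species), lineages within a species-tree branch of duration `t`
coalescent units (CU) coalesce in pairs at rate 1 per pair, and lineages
surviving to the root coalesce with probability one above it. One CU is the
number of generations divided by the (haploid-scaled) effective population
size. Under this model the probability vector `u = (u₁ … u₁₅)` of the 15
unrooted gene-tree topologies on five taxa depends on the rooted species
tree topology and its internal branch lengths — terminal branch lengths are
irrelevant when a single allele is sampled per species — and the *pattern*
of equalities and inequalities among the `uᵢ` depends only on the rooted
topology's shape. These patterns identify the rooted topology, which is the
basis of the estimator.

Rooting is purely topological: gene-tree branch lengths are ignored, so
deviations from a molecular clock have no effect (a property asserted by
test).

## Topology indexing

Unrooted quintets are encoded by their two cherry bipartitions (two
disjoint leaf pairs), ordered lexicographically over the reference leaves
`a..e` — index 1..15. Rooted quintets are numbered 1..105 as
`(unrooted−1)·7 + edge`, with edges numbered by a deterministic post-order
of the tree re-oriented away from its lexicographically smallest leaf. All
orderings are functions of the labeled topology only, so results are
reproducible regardless of newick rotation. Shape census: 60 caterpillar,
30 balanced, 15 pseudo-caterpillar.

The classical `u₁ … u₁₅` numbering used in the invariant literature is
pinned to cherry pairs in `adr_tables.py`. Most of it is forced: `u₁` is
the unrooted topology of the reference trees; the symmetry groups of the
three reference rooted trees force the pair classes `{u₄,u₁₃}`, `{u₅,u₁₂}`,
`{u₆,u₉}`, `{u₈,u₁₁}`; the inequality directions separate `u₂` from `u₃`.
Index choices the structures never distinguish (the order within pairs, and
`{u₇,u₁₀,u₁₄,u₁₅}`) are fixed lexicographically.

## The invariant/inequality tables

Three base structures are stored as literal data, one per shape, on the
reference labelings `((((a,b),c),d),e)`, `(((a,b),c),(d,e))` and
`(((a,b),(d,e)),c)`; the other 102 are generated by leaf permutation
(cached at first use). Each structure is a partition of {1..15} into
equivalence classes plus a set of covering order relations `c > c′`.

The stored orders are the transitive reductions of the partial orders that
hold for *all* positive branch lengths:

* caterpillar: `u₁>u₂`, `u₁>{u₄,u₁₃}`, `u₃>u₂`, `u₃>{u₆,u₉}`,
  `u₂>{u₅,u₁₂}`, `{u₄,u₁₃}>{u₅,u₁₂}`, `{u₆,u₉}>{u₅,u₁₂}`,
  `{u₅,u₁₂}>{rest}`;
* balanced: `u₁` above `{u₂,u₃}` and `{u₄,u₁₃}`, both above the middle
  four, middle four above the bottom six;
* pseudo-caterpillar: `u₁` above the three pairs, each pair above the
  bottom eight.

These were validated against an exact, independently implemented
computation of quintet distributions (`tests/_exact_msc.py`): coalescent
histories are enumerated branch by branch, with the probability of a
specific ordered merge sequence within a branch equal to
`g(m, m−i, t) · Π 1/C(mⱼ,2)`, where `g` is the lineage-count transition
probability of the death chain (computed by matrix exponential). Across a
5³ grid of branch lengths (0.05–2.5 CU), within-class equalities hold to
1e−16 and every stored order relation has a positive margin; relations
*outside* the stored closure change sign somewhere on the grid, so the
stored sets are exactly the universally valid ones. Three published
checksums pin the transcription: invariant terms `Σ C(|c|,2)` = 18/23/31,
inequality terms `Σ_{c>c′} |c||c′|` = 28/44/54, and the weighted counts —
independent within-class constraints `Σ(|c|−1)` plus `1/|c′|`-scaled
inequality terms `Σ|c|` — equal 19/20/19.

## Cost functions

The production cost (variant 4) is the normalized invariants+inequalities
penalty given in the README. Accumulation is plain double precision with
the hinge at exactly zero — costs are only compared, never tested for
equality, so no internal tolerance is applied. Inputs must be normalized
frequency vectors (callers normalize explicitly; tallies do so by
construction). Ablation variants: variant 1 drops the inequality penalty,
variant 2 drops the normalization. Variant 3, an alternative inequality
normalization, is shipped as an explicitly experimental stand-in (terms
divided by the larger class size) behind an opt-in flag, because the
original weighting for this ablation is not reproduced here; it plays no
role in defaults or tests beyond interface checks.

All 105 costs for a distribution are evaluated vectorized from
precomputed term tables (pairs + weights, padded rectangular arrays), which
makes scoring many subsets cheap.

## Rooting search

Five taxa: tally `û` once, score the 7 rootings, return the argmin. Ties
(scores within 1e−12 of the minimum) select the lowest canonical edge id
and set a tie flag — the uniform distribution, for example, scores 0 on
every rooting.

Larger trees: gene trees are encoded once as bitmask clade lists over the
species taxa; the empirical distribution of any five-taxon subset is then
pure integer arithmetic (vectorized over all gene trees at once). Gene
trees missing any of a subset's taxa are excluded from that subset's
numerator and denominator; restrictions with polytomies are dropped and
logged; subsets with no support are skipped (all subsets empty is an
error). Per subset, the 105 costs are computed once and each of the `2n−3`
candidates looks up the cost of the rooted quintet it induces — candidates
rooted on edges invisible to a subset induce the same quintet, so at most 7
distinct lookups occur per subset, and cached scoring provably equals naive
recomputation (asserted against a restrict-and-rescore oracle at n = 6).

The linear encoding selects, for each internal edge of the unrooted
topology, the nearest leaf in each of the four subtrees hanging off the
edge plus the nearest remaining leaf (ties broken lexicographically),
giving at most `n−3` distinct subsets. This is a documented default
strategy satisfying the `O(n)`-subsets/`O(kn)`-time contract and covering
every internal edge; it reduces to the single subset at `n = 5`.

## Simulator

`simulate_gene_trees` draws gene trees by standard backward-in-time
coalescence within the model tree, with node ages accumulated on the
species-tree clock so that output branch lengths are in CU even for
non-ultrametric models. A single `SeedSequence` per call is split into one
child stream per gene, so results do not depend on consumption order.
Unspecified terminal branch lengths default to 1 CU (they cannot affect
topologies); unspecified or non-positive internal lengths are errors.
Simulated frequencies match the exact coalescent distribution
(chi-square goodness of fit at k = 50 000 in the suite).

What the generator emulates — and what it does not: it produces *true* gene
trees under ILS only. Real datasets add gene tree estimation error (GTEE)
from finite sequences; a controllable stand-in is provided as random NNI
perturbation (`nni_perturb`, one move per tree with fixed probability) and
clock deviation as lognormal branch rescaling (`perturb_clock`). Passing
tests therefore demonstrate correctness of the method under the MSC with
true gene trees; they do not quantify robustness to the correlated,
heterogeneous estimation error of real sequence data.

## Study conditions used by the test suite

Chosen once as representative desk-scale regimes: reference-shape recovery
uses 0.5-CU internal branches and k = 10⁵ gene trees; the category-bias
comparison draws 500 model trees uniformly over the 105 rooted quintets
with internal branches U(0.2, 1.0) CU and k = 800; the ten-taxon study uses
20 random model trees with internal branches U(0.5, 1.0) CU and k = 1000,
which lands at 33–46% average discordance — moderate ILS. All stochastic
tests fix seed 42.

## Known limitations

* **Boundary degeneracy.** The true distribution of a *balanced* quintet
  satisfies all the (weak) constraints of the two adjacent caterpillar
  rootings as well — the theory separates them only through strict
  inequalities (`u₂>u₃` strict for the caterpillar versus `u₂=u₃` for the
  balanced tree), which a hinge penalty cannot detect. Both rootings then
  score exactly zero at the true distribution, and under sampling noise the
  caterpillar competitor often wins regardless of k (measured ~73% of
  multinomial draws at 0.5-CU branches; the normalization reduces this —
  the ablation costs essentially never recover a balanced tree). This is
  faithful behavior of the cost being implemented; whether the estimator is
  statistically consistent is an open question, and balanced-shape
  rootings should be treated with caution when the competing costs are
  within the noise floor (compare the per-candidate scores, not just the
  argmin).
* Only single-allele sampling is supported; no gene duplication/loss or
  hybridization, no sequence-level simulation, no support values on the
  inferred root.
* The linear encoding is a documented default subset scheme, not a
  transcription of any published one; the strategy is isolated so an
  alternative can be added without interface changes.
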