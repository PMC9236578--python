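"""Inspect the coalescent invariant/inequality structures behind the cost.

Every rooted five-taxon species tree shape (caterpillar, balanced,
pseudo-caterpillar) determines a partition of the 15 unrooted quintet
gene-tree probabilities into equivalence classes, plus inequalities between
classes.  The penalty-term counts below explain the need for the 1/|c|
normalization: without it the three shapes contribute 46/67/85 raw terms
and the search is biased toward caterpillar rootings.
"""
from quintet_rooting.adr_tables import base_structure, count_penalty_terms
from quintet_rooting.quintets import SHAPES

for shape in SHAPES:
    structure = base_structure(shape)
    counts = count_penalty_terms(structure)
    classes = sorted((sorted(c) for c in structure.classes), key=len)
    print(f"{shape}:")
    print(f"  classes (topology indices): {classes}")
    print(f"  invariant terms:  {counts.invariant_terms}")
    print(f"  inequality terms: {counts.inequality_terms}")
    print(f"  total raw terms:  {counts.total}")
    print(f"  weighted total:   {counts.weighted_total}")
# The weighted totals (19/20/19) are nearly equal across shapes, which is
# what removes the category bias from the rooting search.
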