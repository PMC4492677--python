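"""Classify fold changes and compute category / genome-fraction summaries.

Builds a small expression matrix with known ratio-scale fold changes,
applies the inclusive >=2-fold / <=0.5-fold significance rule, and prints
the per-category percentages and the genome-wide altered fractions, plus
natural-log heat values for display.
"""

import numpy as np

from tfcoherence import (
    CategoryMap,
    ExpressionMatrix,
    category_percentages,
    classify_fold_changes,
    genome_fraction_altered,
    heat_values,
)

# ratio-scale fold changes for 6 genes at two times (stored as log2)
ratios = np.array([
    [80.0, 12.0],   # entA-like: strong induction
    [3.0, 2.0],     # fepA-like: moderate induction (2.0 is called up)
    [1.5, 1.9],     # below threshold both times
    [0.5, 0.25],    # repressed (0.5 is called down)
    [1.0, 1.0],     # unchanged
    [4.0, 0.4],     # up then down
])
genes = ["entA", "fepA", "ydhX", "ftnA", "gapA", "yodA"]
expr = ExpressionMatrix(gene_ids=genes, time_points_min=[10.0, 120.0],
                        values=np.log2(ratios))
cats = CategoryMap({
    "entA": "iron transport and acquisition",
    "fepA": "iron transport and acquisition",
    "ftnA": "iron transport and acquisition",
    "ydhX": "Fe-S proteins",
    "yodA": "stress response",
})  # gapA deliberately uncategorised

table = classify_fold_changes(expr, cats)
print(table.to_string(index=False))

print("\nper-category percentages (denominator: genes in the category):")
print(category_percentages(table).to_string(index=False))

print("\ngenome fraction altered (denominator: genome_size=100):")
print(genome_fraction_altered(table, genome_size=100).to_string(index=False))

print("\nheat values, ln(fold change):")
print(heat_values(table).round(3).to_string())
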