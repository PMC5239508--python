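"""Screen differentially expressed genes and check the arms separate.

A gene is a DEG when |log2 fold change| > 0.5 and p < 0.05 (two-sided
pooled t-test on the log2 intensities) — strict inequalities on both.
"""

import netpharm as nh
from netpharm.expression import ExpressionMatrix, cut_clusters

expr, *_ , truth = nh.simulate_all(nh.ScenarioConfig(seed=1))

stats = nh.compute_gene_stats(expr, "model", "control")
screened = nh.screen_degs(stats, lfc_threshold=0.5, p_threshold=0.05)
counts = nh.deg_counts(screened)
degs = nh.dysregulated_genes(screened)

print(f"disease contrast (model vs control): {counts['up']} up, {counts['down']} down")
print(f"planted disease genes recovered    : "
      f"{len(degs & truth.disease_genes)}/{len(truth.disease_genes)}")

# QC: hierarchical clustering of the two arms over the DEGs should give
# two pure clusters, and PC1 should separate the arms.
keep = [s for s in expr.sample_ids if expr.arm_of[s] in ("model", "control")]
sub = ExpressionMatrix(values=expr.values[keep], arm_of=expr.arm_of[keep])
order, heights, z = nh.cluster_samples(sub, degs)
labels = cut_clusters(z, 2, keep)
print(f"dendrogram leaf order              : {order}")
print(f"two-cluster cut                    : {labels}")
scores, fracs = nh.pca_samples(sub, degs)
print(f"PC1 variance fraction              : {fracs[0]:.2f}")
print(scores.round(2))
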