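"""Generate a synthetic five-arm study with planted ground truth.

The generator emulates a goiter drug study: control and disease-model
arms, a full-formula treatment arm and two deleted-herb arms, three
replicates each, plus a scored gene-interaction network, pathway gene
sets and a compound fingerprint library — everything the inference chain
needs, with the truth recorded for later comparison.
"""

import netpharm as nh

cfg = nh.ScenarioConfig(seed=1)
expr, edges, pathways, fps, ref, known, truth = nh.simulate_all(cfg)

print(f"expression matrix : {expr.values.shape[0]} genes x {expr.values.shape[1]} samples")
print(f"arms              : {expr.arms()}")
print(f"interaction edges : {len(edges)} scored pairs "
      f"(scores {edges.combined_score.min()}..{edges.combined_score.max()})")
print(f"pathways          : {len(pathways)} sets, planted = {truth.enriched_pathway_id}")
print(f"compound library  : {len(fps)} fingerprints, {len(ref)} reference drugs")
print()
print(f"planted disease genes        : {len(truth.disease_genes)}")
print(f"  reversed by full formula   : {len(truth.reversed_by_full)}")
print(f"  reversed by deleted-herb   : {len(truth.reversed_by_minus_herb)}")
print(f"  planted hub module         : {sorted(truth.planted_hub_genes)}")
# The containment chain (minus-herb ⊆ full ⊆ disease) encodes the study
# logic: removing a herb can only weaken, never extend, the reversal.
assert truth.reversed_by_minus_herb <= truth.reversed_by_full <= truth.disease_genes
print("\ncontainment chain holds: minus-herb ⊆ full-formula ⊆ disease genes")
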