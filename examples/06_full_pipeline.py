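"""Run the whole inference chain and compare against the planted truth.

Disease DEGs -> disease network hubs -> treatment DEGs + putative targets
+ known genes -> candidate network -> two-stage major hubs (the candidate
targets) -> enrichment, reversal classification and herb-pair core genes.
"""

import netpharm as nh

cfg = nh.ScenarioConfig(seed=1)
expr, edges, pathways, fps, ref, known, truth = nh.simulate_all(cfg)
res = nh.run_stages(expr, edges, pathways, fps, ref, [("synthetic", known)])
stages = res["report"]["stages"]

print(f"disease DEGs        : {stages['disease_degs']['up']} up / "
      f"{stages['disease_degs']['down']} down")
print(f"disease network     : {stages['disease_network']['n_nodes']} nodes, "
      f"{stages['disease_network']['n_edges']} edges; "
      f"{stages['disease_hubs']['n_hubs']} degree hubs")
print(f"treatment DEGs      : {stages['treatment_degs']['up']} up / "
      f"{stages['treatment_degs']['down']} down")
print(f"putative targets    : {stages['target_prediction']['n_putative_targets']}")
print(f"candidate network   : {stages['candidate_network']['n_nodes']} nodes, "
      f"{stages['candidate_network']['n_edges']} edges")
print(f"candidate targets   : {stages['major_hubs']['n_candidate_targets']} major hubs")

targets = res["candidate_targets"]
goal = truth.planted_hub_genes & truth.reversed_by_full
jac = len(targets & goal) / len(targets | goal)
print(f"  vs planted truth  : Jaccard {jac:.2f} against the reversed hub module")

rev = res["reversal"]["category"].value_counts().to_dict()
print(f"reversal categories : {rev}")
core = res["herb_pair_core_genes"]
expected = truth.reversed_by_full - truth.reversed_by_minus_herb
print(f"herb-pair core genes: {len(core)} "
      f"(Jaccard {len(core & expected)/len(core | expected):.2f} vs planted)")

enr = res["candidate_enrichment"].set_index("pathway_id")
if truth.enriched_pathway_id in enr.index:
    q = enr.loc[truth.enriched_pathway_id, "qvalue"]
    print(f"candidate-target enrichment of planted pathway: q = {q:.2e}")
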