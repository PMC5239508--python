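"""The synthetic study generator and its planted ground truth."""

import dataclasses
from math import comb

import numpy as np
import pytest
from scipy import stats as scistats
from statsmodels.stats import weightstats

import netpharm as nh
from netpharm.synthetic import GroundTruth, ScenarioConfig, _random_bits


class TestScenarioConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_genes": 0},
            {"noise_sd": 0.0},
            {"noise_sd": -1.0},
            {"n_disease_genes": 600},
            {"reversal_fraction_full": 1.2},
            {"similarity_planted": -0.1},
            {"attachment_parameter": 500},
            {"fingerprint_length": 32},
            {"n_network_nodes": 600},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ScenarioConfig(**kwargs)

    def test_rng_streams_are_distinct(self):
        cfg = ScenarioConfig(seed=3)
        a = cfg.rng("expression").integers(0, 2**31, 10)
        b = cfg.rng("network").integers(0, 2**31, 10)
        assert not np.array_equal(a, b)


class TestDeterminismAndContainment:
    def test_same_seed_gives_identical_artifacts(self, small_cfg):
        e1, ed1, pw1, fp1, rf1, kn1, t1 = nh.simulate_all(small_cfg)
        e2, ed2, pw2, fp2, rf2, kn2, t2 = nh.simulate_all(small_cfg)
        assert e1.values.equals(e2.values)
        assert ed1.equals(ed2)
        assert pw1.pathways == pw2.pathways
        assert all(np.array_equal(a, b) for a, b in zip(fp1["bits"], fp2["bits"]))
        assert kn1 == kn2 and t1.to_jsonable() == t2.to_jsonable()

    def test_different_seed_changes_expression(self, small_cfg):
        e1, _ = nh.simulate_expression(small_cfg)
        e2, _ = nh.simulate_expression(dataclasses.replace(small_cfg, seed=99))
        assert not e1.values.equals(e2.values)

    @pytest.mark.parametrize("seed", range(8))
    def test_reversal_containment_chain(self, seed):
        _, truth = nh.simulate_expression(ScenarioConfig(seed=seed))
        assert truth.reversed_by_minus_herb <= truth.reversed_by_full
        assert truth.reversed_by_full <= truth.disease_genes
        assert truth.planted_hub_genes <= truth.disease_genes


class TestSimulateExpression:
    def test_zero_effect_gives_zero_log2fc(self):
        cfg = ScenarioConfig(effect_size=0.0, noise_sd=1e-7, seed=1)
        expr, _ = nh.simulate_expression(cfg)
        stats = nh.compute_gene_stats(expr, "model", "control")
        assert np.abs(stats["log2fc"]).max() < 1e-5

    def test_noise_free_limit_recovers_effect_exactly(self):
        cfg = ScenarioConfig(effect_size=2.0, noise_sd=1e-9, seed=2)
        expr, truth = nh.simulate_expression(cfg)
        stats = nh.compute_gene_stats(expr, "model", "control")
        up = [g for g in truth.disease_genes if stats.loc[g, "log2fc"] > 0]
        assert np.allclose(stats.loc[up, "log2fc"], 2.0, atol=1e-6)
        down = truth.disease_genes - set(up)
        assert np.allclose(stats.loc[sorted(down), "log2fc"], -2.0, atol=1e-6)
        assert len(up) == len(down) == len(truth.disease_genes) // 2

    def test_screen_power_on_planted_genes(self):
        """Monte-Carlo power of the default screen on planted genes >= 0.9."""
        hits = total = 0
        for seed in range(30):
            cfg = ScenarioConfig(seed=seed)
            expr, truth = nh.simulate_expression(cfg)
            degs = nh.dysregulated_genes(
                nh.screen_degs(nh.compute_gene_stats(expr, "model", "control"))
            )
            hits += len(degs & truth.disease_genes)
            total += len(truth.disease_genes)
        assert hits / total >= 0.9

    def test_power_agrees_with_reference_statistics(self):
        """Same power measured with the statsmodels t-test as oracle."""
        hits = total = 0
        for seed in range(5):
            cfg = ScenarioConfig(seed=seed)
            expr, truth = nh.simulate_expression(cfg)
            model = [s for s in expr.sample_ids if expr.arm_of[s] == "model"]
            ctrl = [s for s in expr.sample_ids if expr.arm_of[s] == "control"]
            for g in truth.disease_genes:
                case = expr.values.loc[g, model].to_numpy()
                base = expr.values.loc[g, ctrl].to_numpy()
                _, p, _ = weightstats.ttest_ind(case, base, usevar="pooled")
                lfc = case.mean() - base.mean()
                hits += int(p < 0.05 and abs(lfc) > 0.5)
                total += 1
        assert hits / total >= 0.9

    def test_drug_affected_genes_move_only_under_treatment(self, small_scenario):
        expr, *_, truth = small_scenario
        stats_model = nh.screen_degs(nh.compute_gene_stats(expr, "model", "control"))
        stats_treat = nh.screen_degs(nh.compute_gene_stats(expr, "full", "model"))
        aff = sorted(truth.drug_affected_genes)
        assert (stats_model.loc[aff, "direction"] == "ns").mean() > 0.9
        assert (stats_treat.loc[aff, "direction"] != "ns").mean() > 0.9


class TestSimulateNetwork:
    def test_attachment_one_yields_tree(self):
        cfg = ScenarioConfig(
            n_genes=10, n_disease_genes=1, n_network_nodes=10, attachment_parameter=1
        )
        edges = nh.simulate_network(cfg, GroundTruth())
        assert len(edges) == 9

    def test_scores_are_integers_in_string_range(self, small_scenario):
        _, edges, *_ = small_scenario
        s = edges["combined_score"]
        assert s.between(150, 999).all()
        assert (s == s.astype(int)).all()

    def test_no_planting_matches_plain_preferential_attachment(self):
        """Degree distributions indistinguishable from the reference
        generator when nothing is planted (two-sample KS over 60 seeds)."""
        import networkx as nx

        ours, ref = [], []
        cfg0 = ScenarioConfig(planted_edge_score_boost=0)
        for seed in range(60):
            cfg = dataclasses.replace(cfg0, seed=seed)
            edges = nh.simulate_network(cfg, GroundTruth())
            g = nx.from_pandas_edgelist(edges, "gene_a", "gene_b")
            ours.extend(d for _, d in g.degree())
            h = nx.barabasi_albert_graph(
                cfg.n_network_nodes, cfg.attachment_parameter, seed=10_000 + seed
            )
            ref.extend(d for _, d in h.degree())
        assert scistats.ks_2samp(ours, ref).pvalue > 0.01

    def test_planted_hubs_survive_stage_one_selection(self):
        """All planted hubs pass the 2x-median degree rule in >=95/100 seeds."""
        import pandas as pd

        ok = 0
        for seed in range(100):
            cfg = ScenarioConfig(seed=seed, n_network_nodes=300, hub_extra_edges=20)
            expr, truth = nh.simulate_expression(cfg)
            edges = nh.simulate_network(cfg, truth)
            universe = set(edges["gene_a"]) | set(edges["gene_b"])
            net = nh.build_network(universe, edges)
            prof = pd.DataFrame(
                {"degree": [d for _, d in net.degree()]}, index=list(net.nodes)
            )
            hubs = nh.select_hubs(prof)
            ok += truth.planted_hub_genes <= hubs.hub_ids
        assert ok >= 95

    def test_invalid_attachment_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(n_network_nodes=5, attachment_parameter=5, n_genes=5)


class TestSimulatePathways:
    def test_exact_copy_pathway_attains_combinatorial_minimum(self):
        # a pathway identical to a 30-gene query in a 500-gene universe
        p = nh.hypergeom_pvalue(30, 30, 30, 500)
        assert p == pytest.approx(1 / comb(500, 30), rel=1e-9)

    def test_planted_pathway_overlaps_disease_far_above_chance(self, small_scenario):
        *_, pathways, _, _, _, truth = small_scenario
        name, genes = pathways.pathways[truth.enriched_pathway_id]
        overlap = len(genes & truth.disease_genes)
        assert overlap / len(genes) > 0.5  # chance rate is 20/120

    def test_size_range_respected(self, small_cfg, small_scenario):
        *_, pathways, _, _, _, _ = small_scenario
        lo, hi = small_cfg.pathway_size_range
        for _, genes in pathways.pathways.values():
            assert lo <= len(genes) <= hi

    def test_oversized_range_rejected(self, small_cfg):
        cfg = dataclasses.replace(small_cfg, pathway_size_range=(10, 1000))
        _, truth = nh.simulate_expression(cfg)
        with pytest.raises(ValueError):
            nh.simulate_pathways(cfg, truth)


class TestSimulateCompoundLibrary:
    def test_planted_similarity_closed_form(self, small_cfg):
        """Planted pair Tanimoto equals round(s*b)/(2b - round(s*b)) ~ s/(2-s)."""
        cfg = dataclasses.replace(small_cfg, similarity_planted=0.8)
        _, truth = nh.simulate_expression(cfg)
        fps, ref = nh.simulate_compound_library(cfg, truth)
        ref_by_id = {r.drug_id: r for r in ref.itertuples(index=False)}
        checked = 0
        for row in fps.itertuples(index=False):
            drug = ref_by_id.get("ref" + row.compound_id[3:])
            if drug is None:
                continue
            b = int(row.bits.sum())
            shared = round(0.8 * b)
            expected = shared / (2 * b - shared)
            got = nh.tanimoto(row.bits, drug.bits)
            assert got == pytest.approx(expected, abs=1e-12)
            assert got == pytest.approx(0.8 / (2 - 0.8), abs=0.02)
            checked += 1
        assert checked == cfg.n_compounds // 2

    def test_decoy_similarity_matches_independent_bits_expectation(self):
        """Mean decoy Tanimoto ~ p^2/(2p - p^2) at density p = 0.1."""
        r = np.random.default_rng(0)
        sims = [
            nh.tanimoto(_random_bits(r, 1024), _random_bits(r, 1024))
            for _ in range(1000)
        ]
        assert abs(np.mean(sims) - 0.01 / 0.19) < 0.02

    def test_true_targets_recorded_for_planted_compounds_only(self, small_scenario):
        *_, fps, ref, _, truth = small_scenario
        assert set(truth.compound_true_targets) <= set(fps["compound_id"])
        assert len(truth.compound_true_targets) == len(fps) // 2

    def test_known_genes_drawn_from_disease_genes(self, small_scenario):
        *_, known, truth = small_scenario
        assert set(known) <= truth.disease_genes
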