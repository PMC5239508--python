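"""End-to-end orchestration of the candidate-target inference chain.

Stage order (the full analysis):

1. screen disease DEGs (model vs control);
2. build the median-score-filtered disease network over those DEGs and
   select degree hubs (> 2× median degree);
3. screen treatment-regulating DEGs (full formula vs model);
4. predict putative compound targets by fingerprint similarity and
   aggregate per herb;
5. merge the known disease-gene lists;
6. assemble the disease-gene/drug-gene candidate network from the four
   gene sets, take its degree hubs, and — within the hub-induced
   subnetwork — select the major hubs (above the median of degree,
   betweenness, closeness and k-coreness): the candidate targets;
7. enrich the candidate targets against the pathway collection;
8. classify treatment reversal per gene;
9. intersect the two deleted-herb contrasts into the herb-pair core genes;
10. assemble the herb-pair network (hub disease genes, known genes, core
    genes, herb-pair putative targets) and enrich its nodes.

Everything is deterministic given the inputs; every effective threshold
(including computed medians) is echoed in the report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from . import comparative, enrichment, expression, io, network, targets

logger = logging.getLogger("netpharm.pipeline")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "run_stages"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """File locations, thresholds and dialect switches for one run."""

    # inputs
    expression_path: str = ""
    arm_map_path: str = ""
    edges_path: str = ""
    gmt_path: str = ""
    fingerprints_path: str = ""
    reference_drugs_path: str = ""
    known_gene_paths: list[str] = field(default_factory=list)
    output_dir: str = "netpharm_out"
    # thresholds
    lfc_threshold: float = 0.5
    p_threshold: float = 0.05
    similarity_threshold: float = 0.85
    degree_multiplier: float = 2.0
    q_cutoff: float = 0.05
    # dialect switches
    test: str = "student"  # or "welch"
    closeness: str = "wf"  # or "classic"
    major_hub_scope: str = "hub_subnetwork"  # or "full_network"
    # arm labels
    control_arm: str = "control"
    model_arm: str = "model"
    full_arm: str = "full"
    minus_a_arm: str = "minus_a"
    minus_b_arm: str = "minus_b"
    # herbs forming the deleted pair (for the herb-pair putative targets)
    herb_pair: tuple[str, str] = ("HZ", "GC")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config field(s): {sorted(bad)}")
        if "herb_pair" in raw:
            raw["herb_pair"] = tuple(raw["herb_pair"])
        return cls(**raw)

    def validate(self) -> None:
        for name, v, lo, hi in (
            ("lfc_threshold", self.lfc_threshold, 0, float("inf")),
            ("p_threshold", self.p_threshold, 0, 1),
            ("similarity_threshold", self.similarity_threshold, 0, 1),
            ("degree_multiplier", self.degree_multiplier, 0, float("inf")),
            ("q_cutoff", self.q_cutoff, 0, 1),
        ):
            if not (lo < v <= hi) and not (lo < v < hi):
                raise ValueError(f"{name} out of range: {v}")
        if self.test not in ("student", "welch"):
            raise ValueError(f"unknown test dialect {self.test!r}")
        if self.closeness not in ("wf", "classic"):
            raise ValueError(f"unknown closeness dialect {self.closeness!r}")
        if self.major_hub_scope not in ("hub_subnetwork", "full_network"):
            raise ValueError(f"unknown major_hub_scope {self.major_hub_scope!r}")


def _screen(expr, case, ctrl, cfg) -> pd.DataFrame:
    stats = expression.compute_gene_stats(expr, case, ctrl, test=cfg.test)
    return expression.screen_degs(stats, cfg.lfc_threshold, cfg.p_threshold)


def run_stages(
    expr: expression.ExpressionMatrix,
    edges: pd.DataFrame,
    pathways: enrichment.PathwayCollection,
    fingerprints: pd.DataFrame,
    reference_drugs: pd.DataFrame,
    known_sources: list[tuple[str, list[str]]],
    config: PipelineConfig | None = None,
) -> dict:
    """Run the full inference chain on in-memory inputs.

    Returns a dict of every intermediate and final result keyed by stage
    name, plus a JSON-serialisable ``report``.
    """
    cfg = config or PipelineConfig()
    cfg.validate()
    out: dict = {}
    report: dict = {
        "version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(cfg).items()
        },
        "stages": {},
    }

    def record(stage: str, **info) -> None:
        report["stages"][stage] = info
        logger.info("%s: %s", stage, info)

    def stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:  # annotate with the failing stage
            raise PipelineError(name, str(exc)) from exc

    # 1. disease DEGs
    disease_degs = stage(
        "disease_degs", lambda: _screen(expr, cfg.model_arm, cfg.control_arm, cfg)
    )
    out["disease_degs"] = disease_degs
    counts = expression.deg_counts(disease_degs)
    disease_genes = expression.dysregulated_genes(disease_degs)
    record(
        "disease_degs",
        n_genes=len(disease_degs),
        up=counts["up"],
        down=counts["down"],
        lfc_threshold=cfg.lfc_threshold,
        p_threshold=cfg.p_threshold,
        test=cfg.test,
    )

    # 2. disease network and degree hubs
    disease_net = stage(
        "disease_network", lambda: network.build_network(disease_genes, edges)
    )
    out["disease_network"] = disease_net
    disease_topology = network.compute_topology(disease_net, closeness=cfg.closeness)
    out["disease_topology"] = disease_topology
    hubs = stage(
        "disease_hubs",
        lambda: network.select_hubs(disease_topology, cfg.degree_multiplier),
    )
    out["disease_hubs"] = hubs
    record(
        "disease_network",
        n_nodes=disease_net.number_of_nodes(),
        n_edges=disease_net.number_of_edges(),
        score_median=disease_net.graph.get("score_median"),
    )
    record(
        "disease_hubs",
        n_hubs=len(hubs.hub_ids),
        degree_median=hubs.criterion["median"],
        multiplier=cfg.degree_multiplier,
    )

    # 3. treatment-regulating DEGs
    treat_degs = stage(
        "treatment_degs", lambda: _screen(expr, cfg.full_arm, cfg.model_arm, cfg)
    )
    out["treatment_degs"] = treat_degs
    drug_regulating = expression.dysregulated_genes(treat_degs)
    tcounts = expression.deg_counts(treat_degs)
    record(
        "treatment_degs", n_genes=len(treat_degs), up=tcounts["up"], down=tcounts["down"]
    )

    # 4. putative targets
    predictions = stage(
        "target_prediction",
        lambda: targets.predict_compound_targets(
            fingerprints, reference_drugs, cfg.similarity_threshold
        ),
    )
    out["target_predictions"] = predictions
    herb_of = dict(zip(fingerprints["compound_id"], fingerprints["herb_id"]))
    herb_profile, putative = targets.herb_target_profile(predictions, herb_of)
    out["herb_profile"] = herb_profile
    out["putative_targets"] = putative
    record(
        "target_prediction",
        n_predictions=len(predictions),
        n_putative_targets=len(putative),
        similarity_threshold=cfg.similarity_threshold,
        per_herb={h: len(g) for h, g in herb_profile.items()},
    )

    # 5. known genes
    known = stage("known_genes", lambda: comparative.merge_known_genes(known_sources))
    out["known_genes"] = known
    record("known_genes", n_genes=len(known.gene_ids))

    # 6. candidate network and two-stage hub selection
    cand_net = stage(
        "candidate_network",
        lambda: network.assemble_candidate_network(
            hubs.hub_ids, known.gene_ids, drug_regulating, putative, edges
        ),
    )
    out["candidate_network"] = cand_net
    cand_topology = network.compute_topology(cand_net, closeness=cfg.closeness)
    cand_hubs = stage(
        "candidate_hubs",
        lambda: network.select_hubs(cand_topology, cfg.degree_multiplier),
    )
    hub_subnet = network.induce_subnetwork(cand_net, cand_hubs.hub_ids)
    out["hub_subnetwork"] = hub_subnet
    if cfg.major_hub_scope == "hub_subnetwork":
        major_profile = network.compute_topology(hub_subnet, closeness=cfg.closeness)
    else:
        major_profile = cand_topology.loc[sorted(cand_hubs.hub_ids)]
    major = stage("major_hubs", lambda: network.select_major_hubs(major_profile))
    out["candidate_targets"] = major.hub_ids
    record(
        "candidate_network",
        n_nodes=cand_net.number_of_nodes(),
        n_edges=cand_net.number_of_edges(),
        score_median=cand_net.graph.get("score_median"),
    )
    record(
        "candidate_hubs",
        n_hubs=len(cand_hubs.hub_ids),
        degree_median=cand_hubs.criterion["median"],
        hub_subnetwork_nodes=hub_subnet.number_of_nodes(),
        hub_subnetwork_edges=hub_subnet.number_of_edges(),
    )
    record(
        "major_hubs",
        n_candidate_targets=len(major.hub_ids),
        metric_medians=major.criterion["medians"],
        scope=cfg.major_hub_scope,
    )

    # 7. enrichment of candidate targets
    if major.hub_ids & set(pathways.universe):
        cand_enrich = stage(
            "candidate_enrichment",
            lambda: enrichment.enrich_pathways(major.hub_ids, pathways),
        )
    else:
        cand_enrich = pd.DataFrame(columns=list(enrichment.RESULT_COLUMNS))
    out["candidate_enrichment"] = cand_enrich
    n_sig = int((cand_enrich["qvalue"] < cfg.q_cutoff).sum()) if len(cand_enrich) else 0
    record(
        "candidate_enrichment",
        n_pathways=len(cand_enrich),
        n_significant=n_sig,
        q_cutoff=cfg.q_cutoff,
    )

    # 8. reversal classification
    reversal = stage(
        "reversal", lambda: comparative.classify_reversal(disease_degs, treat_degs)
    )
    out["reversal"] = reversal
    rev_counts = reversal["category"].value_counts().to_dict()
    record("reversal", **{k: int(v) for k, v in rev_counts.items()})

    # 9. herb-pair core genes
    minus_a = stage(
        "minus_a_degs", lambda: _screen(expr, cfg.minus_a_arm, cfg.full_arm, cfg)
    )
    minus_b = stage(
        "minus_b_degs", lambda: _screen(expr, cfg.minus_b_arm, cfg.full_arm, cfg)
    )
    out["minus_a_degs"], out["minus_b_degs"] = minus_a, minus_b
    core = comparative.herb_pair_core_genes(minus_a, minus_b)
    out["herb_pair_core_genes"] = core
    record(
        "herb_pair_core_genes",
        minus_a_degs=len(expression.dysregulated_genes(minus_a)),
        minus_b_degs=len(expression.dysregulated_genes(minus_b)),
        n_core=len(core),
    )

    # 10. herb-pair network and its enrichment
    pair_putative = set().union(
        *(herb_profile.get(h, set()) for h in cfg.herb_pair)
    ) if herb_profile else set()
    if hubs.hub_ids or known.gene_ids or core or pair_putative:
        pair_net = stage(
            "herb_pair_network",
            lambda: network.assemble_candidate_network(
                hubs.hub_ids, known.gene_ids, core, pair_putative, edges
            ),
        )
    else:
        import networkx as nx

        pair_net = nx.Graph()
    out["herb_pair_network"] = pair_net
    pair_nodes = set(pair_net.nodes)
    if pair_nodes & set(pathways.universe):
        pair_enrich = stage(
            "herb_pair_enrichment",
            lambda: enrichment.enrich_pathways(pair_nodes, pathways),
        )
    else:
        pair_enrich = pd.DataFrame(columns=list(enrichment.RESULT_COLUMNS))
    out["herb_pair_enrichment"] = pair_enrich
    record(
        "herb_pair_network",
        n_nodes=pair_net.number_of_nodes(),
        n_edges=pair_net.number_of_edges(),
        n_enriched=int((pair_enrich["qvalue"] < cfg.q_cutoff).sum())
        if len(pair_enrich)
        else 0,
    )

    out["report"] = report
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """File-based pipeline run: read inputs, run all stages, write every
    intermediate plus a JSON report to ``config.output_dir``.

    Returns the report dict.  A stage failure raises
    :class:`PipelineError` after writing a ``FAILED`` marker naming the
    stage; already-written outputs are retained.
    """
    config.validate()
    for p in (
        config.expression_path,
        config.arm_map_path,
        config.edges_path,
        config.gmt_path,
        config.fingerprints_path,
        config.reference_drugs_path,
        *config.known_gene_paths,
    ):
        if p and not Path(p).exists():
            raise FileNotFoundError(p)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    expr = io.read_expression(config.expression_path, config.arm_map_path)
    edges = io.read_edges(config.edges_path)
    pathways = io.read_gmt(config.gmt_path)
    fingerprints = io.read_fingerprints(config.fingerprints_path)
    reference = io.read_reference_drugs(config.reference_drugs_path)
    known_sources = [
        comparative.load_known_gene_list(p) for p in config.known_gene_paths
    ] or comparative.builtin_known_gene_sources()

    try:
        res = run_stages(
            expr, edges, pathways, fingerprints, reference, known_sources, config
        )
    except PipelineError as exc:
        (outdir / "FAILED").write_text(f"{exc.stage}\n{exc}\n")
        raise

    io.write_deg_table(res["disease_degs"], outdir / "disease_degs.tsv")
    io.write_deg_table(res["treatment_degs"], outdir / "treatment_degs.tsv")
    io.write_deg_table(res["minus_a_degs"], outdir / "minus_a_degs.tsv")
    io.write_deg_table(res["minus_b_degs"], outdir / "minus_b_degs.tsv")
    io.write_network(res["disease_network"], outdir / "disease_network.tsv")
    io.write_network(
        res["candidate_network"],
        outdir / "candidate_network.tsv",
        outdir / "candidate_network_nodes.tsv",
    )
    io.write_network(res["hub_subnetwork"], outdir / "hub_subnetwork.tsv")
    io.write_network(
        res["herb_pair_network"],
        outdir / "herb_pair_network.tsv",
        outdir / "herb_pair_network_nodes.tsv",
    )
    res["target_predictions"].to_csv(
        outdir / "target_predictions.tsv", sep="\t", index=False
    )
    res["reversal"].to_csv(outdir / "reversal.tsv", sep="\t", index_label="gene_id")
    res["candidate_enrichment"].to_csv(
        outdir / "candidate_enrichment.tsv", sep="\t", index=False
    )
    res["herb_pair_enrichment"].to_csv(
        outdir / "herb_pair_enrichment.tsv", sep="\t", index=False
    )
    for name in ("candidate_targets", "herb_pair_core_genes"):
        (outdir / f"{name}.txt").write_text(
            "".join(f"{g}\n" for g in sorted(res[name]))
        )

    report = res["report"]
    report["generated_at"] = datetime.now(timezone.utc).isoformat()
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
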