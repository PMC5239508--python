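"""Synthetic study generator with planted ground truth.

Emulates the five-arm goiter study design — normal control, disease model,
full herbal formula, and two deleted-herb variants, three replicates each —
together with the auxiliary inputs the inference chain consumes:

- a group-structured log2-intensity expression matrix with planted disease
  genes (half up-, half down-shifted in the model arm) and planted
  treatment reversal (the full formula returns most disease genes to
  baseline, each deleted-herb arm returns fewer);
- a scale-free scored interaction network with a planted hub module (a
  clique of disease genes with extra boosted-score spokes) in the STRING
  combined-score dialect;
- pathway gene sets with one pathway planted to overlap the disease genes
  far above chance;
- a compound fingerprint library in which planted compounds share a set
  fraction of their bits with target-annotated reference drugs.

Every artifact derives its own RNG stream from the master seed by a fixed
offset, so adding outputs never perturbs existing ones; identical configs
produce identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import PathwayCollection
from .expression import ExpressionMatrix

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "ARMS",
    "HERBS",
    "simulate_expression",
    "simulate_network",
    "simulate_pathways",
    "simulate_compound_library",
    "simulate_known_genes",
    "simulate_all",
]

#: arm labels of the five-group design
ARMS = ("control", "model", "full", "minus_a", "minus_b")

#: the eleven herbs of the formula (standard pinyin abbreviations)
HERBS = ("HZ", "KB", "FBX", "ZBM", "QP", "CP", "DG", "CX", "DH", "LQ", "GC")

# fixed per-artifact RNG stream offsets (spawn keys off the master seed)
_STREAMS = {"expression": 0, "network": 1, "pathways": 2, "compounds": 3, "known": 4}

_BASELINE_MEAN = 8.0  # log2 intensity location of a typical probe
_BASELINE_SD = 1.5  # spread of per-gene baselines across the genome
_FP_DENSITY = 0.1  # expected set-bit fraction of a random fingerprint

# planted hub-module wiring (see simulate_network)
_SPOKE_DISEASE_FRAC = 0.0  # fraction of hub spokes aimed at disease genes
_NB_EDGES = 1  # neighbourhood edges added per non-hub disease gene
_BOOST_DISEASE_EDGES = True  # boost scores of all disease-disease edges too


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic study.

    Defaults reflect the emulated design: 3 replicates per arm, 500 genes
    of which 50 are disease genes shifted by 2.0 log2-units over noise of
    0.4 log2-units plus 60 off-module treatment-affected genes, a
    genome-wide preferential-attachment interaction network (attachment 3)
    with a 10-gene planted hub module (clique + 25 boosted spokes each),
    20 pathways of 15–40 genes with one planted, and 30 compounds with
    1024-bit fingerprints.
    """

    n_genes: int = 500
    n_per_arm: int = 3
    n_disease_genes: int = 50
    n_drug_affected: int = 60
    effect_size: float = 2.0
    noise_sd: float = 0.4
    reversal_fraction_full: float = 0.9
    reversal_fraction_minus_herb: float = 0.3
    n_network_nodes: int = 500
    attachment_parameter: int = 3
    planted_edge_score_boost: int = 300
    n_planted_hubs: int = 10
    hub_extra_edges: int = 25
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (15, 40)
    n_compounds: int = 30
    fingerprint_length: int = 1024
    similarity_planted: float = 0.95
    n_known_genes: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_per_arm": self.n_per_arm,
            "n_disease_genes": self.n_disease_genes,
            "n_network_nodes": self.n_network_nodes,
            "attachment_parameter": self.attachment_parameter,
            "n_pathways": self.n_pathways,
            "n_compounds": self.n_compounds,
            "fingerprint_length": self.fingerprint_length,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        fracs = {
            "reversal_fraction_full": self.reversal_fraction_full,
            "reversal_fraction_minus_herb": self.reversal_fraction_minus_herb,
            "similarity_planted": self.similarity_planted,
        }
        for name, v in fracs.items():
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_disease_genes > self.n_genes:
            raise ValueError("n_disease_genes cannot exceed n_genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.attachment_parameter >= self.n_network_nodes:
            raise ValueError("attachment_parameter must be < n_network_nodes")
        if self.n_network_nodes > self.n_genes:
            raise ValueError("n_network_nodes cannot exceed n_genes")
        if self.fingerprint_length < 64:
            raise ValueError("fingerprint_length must be at least 64")

    def rng(self, stream: str) -> np.random.Generator:
        """The dedicated RNG stream for one output artifact."""
        return np.random.default_rng([self.seed, _STREAMS[stream]])


@dataclass
class GroundTruth:
    """Planted truth of a synthetic scenario.

    ``reversed_by_minus_herb ⊆ reversed_by_full ⊆ disease_genes`` holds by
    construction.  ``enriched_pathway_id`` and ``compound_true_targets``
    are filled in by :func:`simulate_pathways` and
    :func:`simulate_compound_library` respectively.
    """

    disease_genes: set[str] = field(default_factory=set)
    reversed_by_full: set[str] = field(default_factory=set)
    reversed_by_minus_herb: set[str] = field(default_factory=set)
    planted_hub_genes: set[str] = field(default_factory=set)
    drug_affected_genes: set[str] = field(default_factory=set)
    enriched_pathway_id: str | None = None
    compound_true_targets: dict[str, set[str]] = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "disease_genes": sorted(self.disease_genes),
            "drug_affected_genes": sorted(self.drug_affected_genes),
            "reversed_by_full": sorted(self.reversed_by_full),
            "reversed_by_minus_herb": sorted(self.reversed_by_minus_herb),
            "planted_hub_genes": sorted(self.planted_hub_genes),
            "enriched_pathway_id": self.enriched_pathway_id,
            "compound_true_targets": {
                c: sorted(g) for c, g in sorted(self.compound_true_targets.items())
            },
        }


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:04d}" for i in range(1, n + 1)]


def simulate_expression(config: ScenarioConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Five-arm log2 expression matrix with planted disease and reversal.

    Control-arm values are per-gene baselines plus Gaussian noise.  The
    model arm shifts the planted disease genes by ±``effect_size`` (half
    up, half down).  The full-formula arm returns ``reversal_fraction_full``
    of the disease genes to baseline; each deleted-herb arm returns only
    ``reversal_fraction_minus_herb`` of them (a subset of the full-formula
    reversals, so removing a herb never reverses more than the full
    formula).  In addition, ``n_drug_affected`` non-disease genes are
    shifted identically in every treated arm — off-module drug effects,
    which make the treatment contrast regulate far more genes than the
    disease module alone, as multi-component formulas do.  All remaining
    genes are identically distributed in every arm.
    """
    rng = config.rng("expression")
    genes = _gene_ids(config.n_genes)

    disease = sorted(map(str, rng.choice(genes, size=config.n_disease_genes, replace=False)))
    n_up = config.n_disease_genes // 2
    signs = {g: (+1.0 if i < n_up else -1.0) for i, g in enumerate(disease)}

    n_full = round(config.reversal_fraction_full * config.n_disease_genes)
    rev_full = sorted(map(str, rng.choice(disease, size=n_full, replace=False)))
    n_minus = round(config.reversal_fraction_minus_herb * config.n_disease_genes)
    n_minus = min(n_minus, n_full)
    rev_minus = sorted(map(str, rng.choice(rev_full, size=n_minus, replace=False))) if n_full else []

    # planted hubs live among the disease genes reversed by the full
    # formula: the module the whole pipeline should converge on
    pool = rev_full if len(rev_full) >= min(config.n_planted_hubs, len(disease)) else disease
    n_hubs = min(config.n_planted_hubs, len(pool))
    hubs = sorted(map(str, rng.choice(pool, size=n_hubs, replace=False)))

    baseline = rng.normal(_BASELINE_MEAN, _BASELINE_SD, size=config.n_genes)
    base = pd.Series(baseline, index=genes)

    shift_model = pd.Series(0.0, index=genes)
    for g in disease:
        shift_model[g] = signs[g] * config.effect_size
    non_disease = [g for g in genes if g not in set(disease)]
    n_aff = min(config.n_drug_affected, len(non_disease))
    affected = sorted(map(str, rng.choice(non_disease, size=n_aff, replace=False)))
    aff_sign = rng.choice([-1.0, 1.0], size=n_aff)
    shift_drug = pd.Series(0.0, index=genes)
    for g, s in zip(affected, aff_sign):
        shift_drug[g] = s * config.effect_size

    shift_full = shift_model.copy()
    shift_full[list(rev_full)] = 0.0
    shift_full += shift_drug
    shift_minus = shift_model.copy()
    shift_minus[list(rev_minus)] = 0.0
    shift_minus += shift_drug

    arm_shift = {
        "control": pd.Series(0.0, index=genes),
        "model": shift_model,
        "full": shift_full,
        "minus_a": shift_minus,
        "minus_b": shift_minus,
    }

    cols: dict[str, np.ndarray] = {}
    arm_of: dict[str, str] = {}
    for arm in ARMS:
        mean = base + arm_shift[arm]
        for rep in range(1, config.n_per_arm + 1):
            sid = f"{arm}_{rep}"
            cols[sid] = mean.to_numpy() + rng.normal(
                0.0, config.noise_sd, size=config.n_genes
            )
            arm_of[sid] = arm

    values = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    truth = GroundTruth(
        disease_genes=set(disease),
        reversed_by_full=set(rev_full),
        reversed_by_minus_herb=set(rev_minus),
        planted_hub_genes=set(hubs),
        drug_affected_genes=set(affected),
    )
    return ExpressionMatrix(values=values, arm_of=arm_of), truth


def simulate_network(config: ScenarioConfig, truth: GroundTruth) -> pd.DataFrame:
    """Scored edge table: scale-free backbone plus a planted hub module.

    A preferential-attachment (Barabási–Albert) graph over
    ``n_network_nodes`` gene ids (always including the disease genes)
    carries integer combined scores uniform on [150, 999].  The planted
    hub genes are wired into a clique and each gains ``hub_extra_edges``
    spokes to random other nodes; every edge incident to a planted hub has
    its score boosted by ``planted_edge_score_boost`` (capped at 999), so
    the module survives median-score filtering with degree well above
    twice the median.  With no planted hubs and zero boost the graph is
    plain preferential attachment.
    """
    if not truth.disease_genes <= set(_gene_ids(config.n_genes)):
        raise ValueError("disease genes outside the gene universe")
    rng = config.rng("network")
    genes = _gene_ids(config.n_genes)

    others = [g for g in genes if g not in truth.disease_genes]
    n_extra = config.n_network_nodes - len(truth.disease_genes)
    if n_extra < 0:
        raise ValueError("n_network_nodes smaller than the disease gene set")
    node_ids = sorted(truth.disease_genes) + sorted(
        map(str, rng.choice(others, size=n_extra, replace=False))
    )
    perm = rng.permutation(len(node_ids))
    relabel = {i: node_ids[perm[i]] for i in range(len(node_ids))}

    g = nx.barabasi_albert_graph(
        config.n_network_nodes,
        config.attachment_parameter,
        seed=int(rng.integers(2**31)),
    )
    g = nx.relabel_nodes(g, relabel)
    for u, v in g.edges():
        g[u][v]["combined_score"] = int(rng.integers(150, 1000))

    hubs = sorted(truth.planted_hub_genes)
    hub_set = set(hubs)
    if hubs:
        for i, u in enumerate(hubs):
            for v in hubs[i + 1 :]:
                if not g.has_edge(u, v):
                    g.add_edge(u, v, combined_score=int(rng.integers(150, 1000)))
        non_hubs = [n for n in g.nodes if n not in hub_set]
        disease_non_hubs = [n for n in non_hubs if n in truth.disease_genes]
        for u in hubs:
            # spokes reach across the whole network; a configurable
            # fraction can instead be aimed at the disease neighbourhood
            n_dis = min(
                round(_SPOKE_DISEASE_FRAC * config.hub_extra_edges),
                len(disease_non_hubs),
            )
            spokes = list(rng.choice(disease_non_hubs, size=n_dis, replace=False))
            spokes += list(
                rng.choice(non_hubs, size=config.hub_extra_edges - n_dis, replace=False)
            )
            for v in spokes:
                if not g.has_edge(u, v):
                    g.add_edge(u, v, combined_score=int(rng.integers(150, 1000)))
        # disease-neighbourhood wiring: non-hub disease genes interconnect
        # (a module periphery), so the module is a dense neighbourhood and
        # not a bare clique
        if _NB_EDGES and len(disease_non_hubs) > _NB_EDGES:
            for u in disease_non_hubs:
                peers = rng.choice(
                    [v for v in disease_non_hubs if v != u],
                    size=_NB_EDGES,
                    replace=False,
                )
                for v in peers:
                    if not g.has_edge(u, v):
                        g.add_edge(u, v, combined_score=int(rng.integers(150, 1000)))
        if config.planted_edge_score_boost:
            # every module edge carries a boosted confidence score
            dis = set(truth.disease_genes)
            for u, v in g.edges():
                incident_hub = u in hub_set or v in hub_set
                within_disease = _BOOST_DISEASE_EDGES and u in dis and v in dis
                if incident_hub or within_disease:
                    g[u][v]["combined_score"] = min(
                        999, g[u][v]["combined_score"] + config.planted_edge_score_boost
                    )

    rows = sorted(
        (min(u, v), max(u, v), d["combined_score"]) for u, v, d in g.edges(data=True)
    )
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "combined_score"])


def simulate_pathways(config: ScenarioConfig, truth: GroundTruth) -> PathwayCollection:
    """Pathway collection with one pathway planted on the disease genes.

    The planted pathway draws ~70% of its members from the disease genes
    (far above the chance rate n_disease/n_genes); all other pathways are
    uniform draws from the gene universe.  The planted pathway id is
    recorded on ``truth.enriched_pathway_id``.
    """
    lo, hi = config.pathway_size_range
    if not (0 < lo <= hi):
        raise ValueError(f"invalid pathway_size_range {config.pathway_size_range}")
    if hi > config.n_genes:
        raise ValueError("pathway_size_range exceeds the gene universe")
    rng = config.rng("pathways")
    genes = _gene_ids(config.n_genes)
    disease = sorted(truth.disease_genes)
    others = [g for g in genes if g not in truth.disease_genes]

    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    planted_id = "PW0001"
    for i in range(1, config.n_pathways + 1):
        pid = f"PW{i:04d}"
        size = int(rng.integers(lo, hi + 1))
        if pid == planted_id and disease:
            n_dis = min(len(disease), max(1, round(0.7 * size)))
            members = list(rng.choice(disease, size=n_dis, replace=False))
            if size - n_dis > 0:
                members += list(rng.choice(others, size=size - n_dis, replace=False))
            name = "planted disease pathway"
        else:
            members = list(rng.choice(genes, size=size, replace=False))
            name = f"random pathway {i}"
        pathways[pid] = (name, frozenset(members))

    truth.enriched_pathway_id = planted_id if disease else None
    return PathwayCollection(pathways=pathways, universe=frozenset(genes))


def _random_bits(rng: np.random.Generator, length: int, density: float = _FP_DENSITY) -> np.ndarray:
    bits = rng.random(length) < density
    if not bits.any():  # degenerate at tiny lengths; force one bit
        bits[int(rng.integers(length))] = True
    return bits


def simulate_compound_library(
    config: ScenarioConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compound fingerprints plus a target-annotated reference-drug table.

    Each compound is assigned to one of the eleven herbs.  Half of the
    compounds carry planted targets: a matched reference drug shares
    ``similarity_planted`` of the compound's set bits (its remaining bits
    disjoint, and the two bit counts equal), giving Tanimoto
    s·b/(2b−s·b) = s/(2−s); its annotation is the compound's true target
    set, drawn with a bias toward the planted hub / disease genes so the
    predicted-target stream converges on the same module as the expression
    stream.  The remaining reference drugs are decoys with independent
    random fingerprints and random annotations.
    """
    rng = config.rng("compounds")
    genes = _gene_ids(config.n_genes)
    disease = sorted(truth.disease_genes)
    hubs = sorted(truth.planted_hub_genes)

    fp_rows = []
    ref_rows = []
    truth.compound_true_targets = {}
    n_planted = config.n_compounds // 2
    for i in range(1, config.n_compounds + 1):
        cid = f"cmp{i:03d}"
        herb = HERBS[(i - 1) % len(HERBS)]
        bits = _random_bits(rng, config.fingerprint_length)
        fp_rows.append((cid, herb, bits))
        if i <= n_planted:
            set_idx = np.flatnonzero(bits)
            b = set_idx.size
            n_shared = round(config.similarity_planted * b)
            shared = rng.choice(set_idx, size=n_shared, replace=False)
            ref_bits = np.zeros(config.fingerprint_length, dtype=bool)
            ref_bits[shared] = True
            unset = np.flatnonzero(~bits)
            own = rng.choice(unset, size=b - n_shared, replace=False)
            ref_bits[own] = True
            # true targets: mostly module genes so predictions feed the
            # candidate network where the planted hubs live
            n_t = int(rng.integers(2, 6))
            tgt: set[str] = set()
            for _ in range(n_t):
                u = rng.random()
                if u < 0.5 and hubs:
                    tgt.add(str(rng.choice(hubs)))
                elif u < 0.8 and disease:
                    tgt.add(str(rng.choice(disease)))
                else:
                    tgt.add(str(rng.choice(genes)))
            truth.compound_true_targets[cid] = tgt
            ref_rows.append((f"ref{i:03d}", ref_bits, tuple(sorted(tgt))))
        else:
            decoy_bits = _random_bits(rng, config.fingerprint_length)
            decoy_tgt = tuple(
                sorted(set(rng.choice(genes, size=int(rng.integers(2, 6)), replace=False)))
            )
            ref_rows.append((f"decoy{i:03d}", decoy_bits, decoy_tgt))

    fingerprints = pd.DataFrame(fp_rows, columns=["compound_id", "herb_id", "bits"])
    reference = pd.DataFrame(ref_rows, columns=["drug_id", "bits", "targets"])
    return fingerprints, reference


def simulate_known_genes(config: ScenarioConfig, truth: GroundTruth) -> list[str]:
    """A small 'known disease gene' list sampled from the planted disease
    genes — the stand-in for curated database knowledge."""
    rng = config.rng("known")
    n = min(config.n_known_genes, len(truth.disease_genes))
    return sorted(map(str, rng.choice(sorted(truth.disease_genes), size=n, replace=False)))


def simulate_all(config: ScenarioConfig):
    """Generate every scenario artifact.

    Returns ``(expr, edges, pathways, fingerprints, reference_drugs,
    known_genes, truth)``.
    """
    expr, truth = simulate_expression(config)
    edges = simulate_network(config, truth)
    pathways = simulate_pathways(config, truth)
    fingerprints, reference = simulate_compound_library(config, truth)
    known = simulate_known_genes(config, truth)
    return expr, edges, pathways, fingerprints, reference, known, truth


def with_seed(config: ScenarioConfig, seed: int) -> ScenarioConfig:
    """A copy of ``config`` with a different master seed."""
    return replace(config, seed=seed)
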