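"""Scored gene-interaction networks and two-stage topological hub selection.

Networks are simple undirected :class:`networkx.Graph` objects whose edges
carry a positive ``combined_score`` (STRING-style confidence; the pipeline
treats it as an opaque positive number).  Construction filters a candidate
edge table at the median combined score.  Node importance is summarised by
four topological features — degree, betweenness, closeness and k-coreness —
and hubs are selected in two stages: first every node whose degree strictly
exceeds twice the median degree, then, within the hub-induced subnetwork,
the "major hubs" strictly above the median of all four features.  Major
hubs of the disease-gene/drug-gene network are the candidate drug targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "HubSelection",
    "build_network",
    "compute_topology",
    "select_hubs",
    "select_major_hubs",
    "assemble_candidate_network",
    "induce_subnetwork",
]

METRICS = ("degree", "betweenness", "closeness", "kcoreness")

#: provenance tags used by assemble_candidate_network, in column order
PROVENANCE_TAGS = ("hub_disease", "known", "drug_regulating", "putative_target")


@dataclass
class HubSelection:
    """A hub set together with the criterion that produced it.

    ``criterion`` records the metric medians and multipliers in force so a
    selection can be re-evaluated against the profile it came from.
    """

    hub_ids: set[str]
    criterion: dict = field(default_factory=dict)


def _validate_edges(edges: pd.DataFrame) -> pd.DataFrame:
    required = {"gene_a", "gene_b", "combined_score"}
    missing = required - set(edges.columns)
    if missing:
        raise ValueError(f"edge table missing columns: {sorted(missing)}")
    if len(edges) and (edges["combined_score"] <= 0).any():
        raise ValueError("edge scores must be positive")
    return edges


def _dedupe(edges: pd.DataFrame) -> pd.DataFrame:
    """Drop self-loops; collapse duplicate unordered pairs keeping the
    maximum score (a simple-graph is required downstream)."""
    e = edges.loc[edges["gene_a"] != edges["gene_b"]].copy()
    if e.empty:
        return e
    key = [tuple(sorted((a, b))) for a, b in zip(e["gene_a"], e["gene_b"])]
    e["_key"] = key
    e = e.sort_values("combined_score").drop_duplicates("_key", keep="last")
    e[["gene_a", "gene_b"]] = pd.DataFrame(list(e["_key"]), index=e.index)
    return e.drop(columns="_key")


def build_network(candidate_genes: set[str], edges: pd.DataFrame) -> nx.Graph:
    """Median-score-filtered interaction network over a candidate gene set.

    Edges are restricted to pairs with both endpoints in
    ``candidate_genes``; the median combined score of the restricted edges
    becomes the threshold and edges scoring ≥ that median are kept (the
    median edge itself survives).  Nodes are the endpoints of kept edges.
    The threshold is stored as ``G.graph["score_median"]``.
    """
    edges = _dedupe(_validate_edges(edges))
    cand = set(candidate_genes)
    mask = edges["gene_a"].isin(cand) & edges["gene_b"].isin(cand)
    restricted = edges.loc[mask]
    g = nx.Graph()
    if restricted.empty:
        warnings.warn("no edges among candidate genes; returning empty network")
        g.graph["score_median"] = None
        return g
    median = float(np.median(restricted["combined_score"]))
    kept = restricted.loc[restricted["combined_score"] >= median]
    for a, b, s in kept[["gene_a", "gene_b", "combined_score"]].itertuples(index=False):
        g.add_edge(a, b, combined_score=float(s))
    g.graph["score_median"] = median
    return g


def compute_topology(net: nx.Graph, closeness: str = "wf") -> pd.DataFrame:
    """The four per-node topological features as a DataFrame.

    degree
        incident-edge count.
    betweenness
        unnormalised shortest-path betweenness on the unweighted graph,
        endpoints excluded, each unordered pair counted once.
    closeness
        by default the Wasserman–Faust component-adjusted closeness
        ((r−1)/Σd)·((r−1)/(n−1)) with r = nodes reachable incl. self —
        well-defined on disconnected graphs; ``closeness="classic"``
        switches to the within-component formula.  Isolated nodes score 0.
    kcoreness
        largest k such that the node survives iterative removal of nodes
        of degree < k.
    """
    if closeness not in ("wf", "classic"):
        raise ValueError("closeness must be 'wf' or 'classic'")
    nodes = list(net.nodes)
    deg = dict(net.degree())
    btw = nx.betweenness_centrality(net, normalized=False)
    clo = nx.closeness_centrality(net, wf_improved=(closeness == "wf"))
    core = nx.core_number(net) if nodes else {}
    return pd.DataFrame(
        {
            "degree": [deg[n] for n in nodes],
            "betweenness": [btw[n] for n in nodes],
            "closeness": [clo[n] for n in nodes],
            "kcoreness": [core[n] for n in nodes],
        },
        index=pd.Index(nodes, name="gene_id"),
    )


def select_hubs(profile: pd.DataFrame, multiplier: float = 2.0) -> HubSelection:
    """Nodes whose degree strictly exceeds ``multiplier`` × median degree."""
    if profile.empty:
        raise ValueError("topology profile is empty")
    med = float(np.median(profile["degree"]))
    cut = multiplier * med
    hubs = set(profile.index[profile["degree"] > cut])
    return HubSelection(
        hub_ids=hubs,
        criterion={"metric": "degree", "median": med, "multiplier": multiplier},
    )


def select_major_hubs(profile: pd.DataFrame) -> HubSelection:
    """Nodes strictly above the median of every one of the four features."""
    if profile.empty:
        raise ValueError("topology profile is empty")
    medians = {m: float(np.median(profile[m])) for m in METRICS}
    mask = np.ones(len(profile), dtype=bool)
    for m in METRICS:
        mask &= profile[m].to_numpy() > medians[m]
    return HubSelection(
        hub_ids=set(profile.index[mask]),
        criterion={"medians": medians, "rule": "strictly above all four medians"},
    )


def assemble_candidate_network(
    hub_disease_genes: set[str],
    known_genes: set[str],
    drug_regulating_genes: set[str],
    putative_targets: set[str],
    edges: pd.DataFrame,
) -> nx.Graph:
    """Disease-gene / drug-gene network over the union of the four sets.

    Every union member becomes a node tagged with its provenance labels
    (``provenance`` node attribute, a sorted tuple of tags); edges among
    the union are filtered at their median combined score exactly as in
    :func:`build_network`.  Unlike :func:`build_network`, union nodes
    without a surviving edge are retained as isolated nodes so provenance
    is never lost.
    """
    groups = {
        "hub_disease": set(hub_disease_genes),
        "known": set(known_genes),
        "drug_regulating": set(drug_regulating_genes),
        "putative_target": set(putative_targets),
    }
    universe = set().union(*groups.values())
    if not universe:
        raise ValueError("all four gene sets are empty")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        g = build_network(universe, edges)
    for node in universe:
        tags = tuple(t for t in PROVENANCE_TAGS if node in groups[t])
        if node in g:
            g.nodes[node]["provenance"] = tags
        else:
            g.add_node(node, provenance=tags)
    return g


def induce_subnetwork(net: nx.Graph, node_subset: set[str]) -> nx.Graph:
    """Subnetwork induced on ``node_subset`` with scores preserved.

    Ids absent from the network are dropped with a warning.
    """
    subset = set(node_subset)
    extra = subset - set(net.nodes)
    if extra:
        warnings.warn(f"{len(extra)} subset id(s) not in network; dropped")
    sub = net.subgraph(subset & set(net.nodes)).copy()
    sub.graph.update(net.graph)
    return sub
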