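"""Hypergeometric pathway over-representation with BH control.

Given a query gene set and a pathway collection, each pathway is scored by
the one-sided hypergeometric upper tail P(X ≥ k) — the probability that a
uniformly drawn query of the same size overlaps the pathway at least as
much — and Benjamini–Hochberg q-values are computed across all tested
pathways.  The universe is, by default, every gene annotated to any
pathway in the collection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats as _scistats
from statsmodels.stats.multitest import multipletests

__all__ = ["PathwayCollection", "hypergeom_pvalue", "enrich_pathways"]

RESULT_COLUMNS = (
    "pathway_id",
    "name",
    "overlap",
    "pathway_size",
    "query_size",
    "universe_size",
    "pvalue",
    "qvalue",
    "overlap_genes",
)


@dataclass
class PathwayCollection:
    """Named gene sets over a common gene universe.

    Pathway genes outside the universe are dropped (count recorded in
    ``n_dropped``); pathways left empty after restriction are removed with
    a warning.  If no universe is given it defaults to the union of all
    pathway genes.
    """

    pathways: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str] = field(default=None)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.universe is None:
            self.universe = frozenset().union(
                *(genes for _, genes in self.pathways.values())
            ) if self.pathways else frozenset()
        self.universe = frozenset(self.universe)
        restricted = {}
        dropped = 0
        for pid, (name, genes) in self.pathways.items():
            kept = frozenset(genes) & self.universe
            dropped += len(frozenset(genes)) - len(kept)
            if kept:
                restricted[pid] = (name, kept)
            else:
                warnings.warn(f"pathway {pid!r} empty after universe restriction; removed")
        self.pathways = restricted
        self.n_dropped = dropped

    def __len__(self) -> int:
        return len(self.pathways)


def hypergeom_pvalue(overlap: int, query_size: int, pathway_size: int, universe_size: int) -> float:
    """Upper-tail hypergeometric probability P(X ≥ overlap).

    X counts pathway members in a uniform draw of ``query_size`` genes
    from a universe of ``universe_size`` containing ``pathway_size``
    pathway members.  ``overlap = 0`` gives exactly 1.
    """
    k, n, big_k, big_n = overlap, query_size, pathway_size, universe_size
    if not (0 <= k <= min(n, big_k)) or n > big_n or big_k > big_n:
        raise ValueError(
            f"inconsistent counts: overlap={k}, query={n}, pathway={big_k}, universe={big_n}"
        )
    return float(_scistats.hypergeom.sf(k - 1, big_n, big_k, n))


def enrich_pathways(query: set[str], collection: PathwayCollection) -> pd.DataFrame:
    """Over-representation of ``query`` in every pathway of ``collection``.

    The query is first restricted to the collection's universe (an empty
    restricted query is an error).  Rows are ordered by p-value then
    pathway id; q-values are BH-adjusted across all tested pathways.
    """
    q = set(query) & set(collection.universe)
    if not q:
        raise ValueError("query has no genes in the pathway universe")
    big_n = len(collection.universe)
    n = len(q)
    rows = []
    for pid, (name, genes) in collection.pathways.items():
        ov = q & genes
        p = hypergeom_pvalue(len(ov), n, len(genes), big_n)
        rows.append(
            (pid, name, len(ov), len(genes), n, big_n, p, ";".join(sorted(ov)))
        )
    out = pd.DataFrame(
        rows,
        columns=[c for c in RESULT_COLUMNS if c != "qvalue"],
    )
    out["qvalue"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    out = out.sort_values(["pvalue", "pathway_id"]).reset_index(drop=True)
    return out[list(RESULT_COLUMNS)]
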