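"""Differential-expression screening of a log2 expression matrix.

The substrate is a genes × samples matrix of log2 intensities with each
sample assigned to one experimental arm (control, disease model, full
herbal formula, or a deleted-herb variant).  Per-gene contrast statistics
between two arms are a mean log2 difference and a two-sided two-sample
location test; a gene is called differentially expressed (DEG) when it
passes joint fold-change and p-value thresholds with strict inequalities.
Hierarchical clustering and PCA of the samples over a gene subset serve as
quality-control views of a screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import cluster as _scicluster
from scipy import stats as _scistats

__all__ = [
    "ExpressionMatrix",
    "compute_gene_stats",
    "screen_degs",
    "deg_counts",
    "dysregulated_genes",
    "cluster_samples",
    "pca_samples",
]

#: variance floor used when both arms of a gene are exactly constant but
#: their means differ; avoids a 0/0 statistic without fabricating
#: significance for genuinely flat genes.
VARIANCE_FLOOR = 1e-12

DIRECTIONS = ("up", "down", "ns")


@dataclass
class ExpressionMatrix:
    """Log2-intensity expression matrix with an arm label per sample.

    Parameters
    ----------
    values
        DataFrame of log2 intensities, index = gene ids, columns = sample
        ids.  All values must be finite; duplicate gene or sample ids are
        rejected.
    arm_of
        Mapping (Series or dict) sample id -> arm label covering every
        sample exactly once.
    """

    values: pd.DataFrame
    arm_of: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        if isinstance(self.arm_of, dict):
            self.arm_of = pd.Series(self.arm_of)
        v = self.values
        if v.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if v.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        if not np.isfinite(v.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains non-finite values")
        missing = set(v.columns) - set(self.arm_of.index)
        if missing:
            raise ValueError(f"samples without arm label: {sorted(missing)}")
        self.arm_of = self.arm_of.loc[list(v.columns)]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def arms(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.arm_of:
            seen.setdefault(a, None)
        return list(seen)

    def arm_samples(self, arm: str) -> list[str]:
        return [s for s in self.sample_ids if self.arm_of[s] == arm]


def _arm_matrix(expr: ExpressionMatrix, arm: str, min_n: int = 2) -> np.ndarray:
    samples = expr.arm_samples(arm)
    if not samples:
        raise ValueError(f"unknown arm label: {arm!r}")
    if len(samples) < min_n:
        raise ValueError(
            f"arm {arm!r} has {len(samples)} sample(s); at least {min_n} required"
        )
    return expr.values[samples].to_numpy(dtype=float)


def compute_gene_stats(
    expr: ExpressionMatrix,
    case_arm: str,
    control_arm: str,
    test: str = "student",
) -> pd.DataFrame:
    """Per-gene contrast statistics for ``case_arm`` versus ``control_arm``.

    Values are already log2, so the log2 fold change is simply
    mean(case) − mean(control).  The p-value comes from a two-sided
    two-sample t-test: pooled-variance Student by default (exact under the
    equal-variance null, which matters at n = 3 per arm), or Welch via
    ``test="welch"``.

    Returns a DEG table (DataFrame indexed by gene id) with columns
    ``log2fc``, ``pvalue`` and ``direction``; directions are all ``"ns"``
    until :func:`screen_degs` assigns them.
    """
    if test not in ("student", "welch"):
        raise ValueError(f"unknown test {test!r}; use 'student' or 'welch'")
    case = _arm_matrix(expr, case_arm)
    ctrl = _arm_matrix(expr, control_arm)

    log2fc = case.mean(axis=1) - ctrl.mean(axis=1)
    res = _scistats.ttest_ind(case, ctrl, axis=1, equal_var=(test == "student"))
    pvalue = np.asarray(res.pvalue, dtype=float)

    # Genes constant within both arms: t is 0/0.  Equal means -> p = 1;
    # otherwise recompute with a variance floor so the call is finite.
    flat = (case.var(axis=1, ddof=1) == 0) & (ctrl.var(axis=1, ddof=1) == 0)
    if flat.any():
        n1, n2 = case.shape[1], ctrl.shape[1]
        se = np.sqrt(VARIANCE_FLOOR / n1 + VARIANCE_FLOOR / n2)
        t = log2fc[flat] / se
        df = n1 + n2 - 2
        p_flat = 2.0 * _scistats.t.sf(np.abs(t), df)
        p_flat[log2fc[flat] == 0] = 1.0
        pvalue[flat] = p_flat

    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": np.clip(pvalue, 0.0, 1.0),
            "direction": "ns",
        },
        index=pd.Index(expr.gene_ids, name="gene_id"),
    )


def screen_degs(
    stats: pd.DataFrame,
    lfc_threshold: float = 0.5,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Assign up/down/ns calls with strict-inequality thresholds.

    ``up``   : log2fc >  lfc_threshold and pvalue < p_threshold
    ``down`` : log2fc < −lfc_threshold and pvalue < p_threshold
    ``ns``   : everything else (boundary values included).

    The default thresholds (0.5, 0.05) define the screening dialect; the
    stricter |log2fc| > 1 dialect is obtained by passing
    ``lfc_threshold=1.0``.
    """
    for name, thr in (("lfc_threshold", lfc_threshold), ("p_threshold", p_threshold)):
        if not np.isfinite(thr) or thr <= 0:
            raise ValueError(f"{name} must be a positive finite number, got {thr}")
    out = stats.copy()
    sig = out["pvalue"] < p_threshold
    out["direction"] = "ns"
    out.loc[sig & (out["log2fc"] > lfc_threshold), "direction"] = "up"
    out.loc[sig & (out["log2fc"] < -lfc_threshold), "direction"] = "down"
    return out


def deg_counts(screened: pd.DataFrame) -> dict[str, int]:
    """Counts of up/down/ns calls in a screened DEG table."""
    c = screened["direction"].value_counts()
    return {d: int(c.get(d, 0)) for d in DIRECTIONS}


def dysregulated_genes(screened: pd.DataFrame) -> set[str]:
    """Gene ids called up or down (the DEG set of a contrast)."""
    return set(screened.index[screened["direction"].isin(["up", "down"])])


def cluster_samples(
    expr: ExpressionMatrix, gene_subset: set[str]
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Agglomerative (average-linkage) clustering of samples on Euclidean
    distance over ``gene_subset``.

    Samples are processed in lexicographic id order so that exact distance
    ties break deterministically toward the lexicographically first pair.

    Returns ``(leaf_order, merge_heights, linkage_matrix)`` where
    ``leaf_order`` is the dendrogram leaf order as sample ids and
    ``merge_heights`` the heights of the n−1 merges.
    """
    subset = [g for g in expr.gene_ids if g in gene_subset]
    if not subset:
        raise ValueError("gene_subset is empty or contains no known genes")
    samples = sorted(expr.sample_ids)
    mat = expr.values.loc[subset, samples].to_numpy(dtype=float).T
    z = _scicluster.hierarchy.linkage(mat, method="average", metric="euclidean")
    order = _scicluster.hierarchy.leaves_list(z)
    return [samples[i] for i in order], z[:, 2].copy(), z


def cut_clusters(linkage_matrix: np.ndarray, k: int, sample_ids: list[str]) -> dict[str, int]:
    """Flat cluster labels for a ``cluster_samples`` result cut at k groups."""
    labels = _scicluster.hierarchy.fcluster(linkage_matrix, t=k, criterion="maxclust")
    return dict(zip(sorted(sample_ids), (int(x) for x in labels)))


def pca_samples(
    expr: ExpressionMatrix, gene_subset: set[str] | None = None, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores on the leading principal components.

    The genes × samples block is gene-centred and decomposed by SVD; the
    returned scores are the sample projections and the variance fractions
    are the squared singular values over their total.  A constant matrix
    yields zero scores with a warning.  Component signs are fixed so the
    largest-magnitude score on each component is positive (determinism).
    """
    genes = expr.gene_ids if gene_subset is None else [
        g for g in expr.gene_ids if g in gene_subset
    ]
    if not genes:
        raise ValueError("gene_subset is empty or contains no known genes")
    if len(expr.sample_ids) < 2:
        raise ValueError("PCA requires at least 2 samples")
    mat = expr.values.loc[genes].to_numpy(dtype=float)
    centred = mat - mat.mean(axis=1, keepdims=True)
    total_var = float((centred**2).sum())
    n_components = min(n_components, len(expr.sample_ids))
    if total_var == 0:
        warnings.warn("expression block has zero variance; PCA scores are all zero")
        scores = np.zeros((len(expr.sample_ids), n_components))
        fracs = np.zeros(n_components)
    else:
        _, s, vt = np.linalg.svd(centred, full_matrices=False)
        scores = (vt[:n_components].T * s[:n_components]).copy()
        for j in range(scores.shape[1]):
            if scores[np.argmax(np.abs(scores[:, j])), j] < 0:
                scores[:, j] *= -1
        fracs = (s[:n_components] ** 2) / total_var
    score_df = pd.DataFrame(
        scores,
        index=pd.Index(expr.sample_ids, name="sample_id"),
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return score_df, fracs
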