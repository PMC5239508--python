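"""Chemical-similarity target prediction for formula compounds.

The working hypothesis is the classic similar-property principle: drugs
with similar chemical structure tend to bind functionally related targets.
Each formula compound carries a binary structural fingerprint; whenever its
Tanimoto similarity to a target-annotated reference drug reaches a
threshold (default 0.85), the reference drug's targets are transferred to
the compound as putative targets.  Predictions aggregate to per-herb target
profiles and a formula-level union.

Fingerprints are consumed as precomputed fixed-length bit vectors (hex
strings in files); no chemistry toolkit is required.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Fingerprint",
    "tanimoto",
    "predict_compound_targets",
    "herb_target_profile",
]

PREDICTION_COLUMNS = ("compound_id", "herb_id", "gene_id", "similarity", "source_drug_id")


@dataclass(frozen=True)
class Fingerprint:
    """A compound's binary structural fingerprint."""

    compound_id: str
    herb_id: str
    bits: np.ndarray  # 1-D bool array

    def __post_init__(self) -> None:
        object.__setattr__(self, "bits", np.asarray(self.bits, dtype=bool))

    @property
    def n_bits(self) -> int:
        return int(self.bits.size)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto (Jaccard) similarity |a∩b| / |a∪b| of two bit vectors.

    Raises on length mismatch and on the undefined all-zero/all-zero case.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.size} vs {b.size}")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        raise ValueError("tanimoto undefined: both fingerprints are all-zero")
    return int(np.logical_and(a, b).sum()) / union


def predict_compound_targets(
    fingerprints: pd.DataFrame,
    reference_drugs: pd.DataFrame,
    threshold: float = 0.85,
) -> pd.DataFrame:
    """Transfer reference-drug targets to structurally similar compounds.

    Parameters
    ----------
    fingerprints
        Compound table with columns ``compound_id``, ``herb_id``, ``bits``
        (bool arrays of one shared length).
    reference_drugs
        Reference table with columns ``drug_id``, ``bits``, ``targets``
        (iterable of gene ids).
    threshold
        Minimum Tanimoto similarity, in (0, 1].  Every (compound, drug)
        pair at or above it emits one row per annotated target gene.

    Returns a prediction table with one row per
    (compound, gene, source drug) and the similarity that licensed it.
    """
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if reference_drugs.empty:
        warnings.warn("empty reference drug table; no targets predicted")
        return pd.DataFrame(columns=list(PREDICTION_COLUMNS))
    rows = []
    ref = list(
        reference_drugs[["drug_id", "bits", "targets"]].itertuples(index=False)
    )
    for comp in fingerprints[["compound_id", "herb_id", "bits"]].itertuples(index=False):
        for drug in ref:
            sim = tanimoto(comp.bits, drug.bits)
            if sim >= threshold:
                for gene in drug.targets:
                    rows.append(
                        (comp.compound_id, comp.herb_id, gene, sim, drug.drug_id)
                    )
    out = pd.DataFrame(rows, columns=list(PREDICTION_COLUMNS))
    return out.drop_duplicates(["compound_id", "gene_id", "source_drug_id"]).reset_index(
        drop=True
    )


def herb_target_profile(
    predictions: pd.DataFrame, herb_of: dict[str, str]
) -> tuple[dict[str, set[str]], set[str]]:
    """Per-herb putative-target sets and the formula-level union.

    ``herb_of`` maps every compound id appearing in ``predictions`` to its
    herb; an unmapped compound is an error naming the compound.  Herbs in
    the map with no predicted targets appear with an empty set, so per-herb
    counts always cover the whole formula.
    """
    profile: dict[str, set[str]] = {h: set() for h in dict.fromkeys(herb_of.values())}
    for comp, gene in zip(predictions["compound_id"], predictions["gene_id"]):
        if comp not in herb_of:
            raise KeyError(f"compound {comp!r} has no herb assignment")
        profile[herb_of[comp]].add(gene)
    formula = set().union(*profile.values()) if profile else set()
    return profile, formula
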