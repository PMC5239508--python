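"""Cross-arm comparisons: treatment reversal, herb-pair core genes, and
known disease-gene merging.

A gene dysregulated in the disease model is *reversed* by a treatment when
the treatment-versus-model contrast moves it in the strictly opposite
direction; same-direction further dysregulation, or no significant
treatment response, counts as not reversed.  Removing one herb from the
formula and contrasting the deleted-herb arm against the full formula
attributes response changes to that herb; genes dysregulated in *both*
deleted-herb contrasts are the herb pair's regulating (core) genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "KnownGeneSet",
    "classify_reversal",
    "herb_pair_core_genes",
    "merge_known_genes",
    "load_known_gene_list",
    "builtin_known_gene_sources",
]

CATEGORIES = ("reversed", "not_reversed", "unaffected")

_OPPOSITE = {"up": "down", "down": "up"}


@dataclass
class KnownGeneSet:
    """A merged, de-duplicated known disease-gene list with provenance."""

    gene_ids: set[str]
    source_of: dict[str, list[str]]


def classify_reversal(model_degs: pd.DataFrame, treat_degs: pd.DataFrame) -> pd.DataFrame:
    """Per-gene reversal category from two screened DEG tables.

    ``model_degs`` is the disease-model-versus-control screen,
    ``treat_degs`` the treatment-versus-model screen, over the same gene
    universe.  Categories:

    - ``unaffected``: not dysregulated in the model (model direction ns);
    - ``reversed``: dysregulated in the model and moved in the strictly
      opposite direction by treatment;
    - ``not_reversed``: dysregulated in the model but not
      counter-directional under treatment.
    """
    missing = set(model_degs.index).symmetric_difference(treat_degs.index)
    if missing:
        raise ValueError(
            f"gene universes differ; {len(missing)} unmatched id(s): "
            f"{sorted(missing)[:10]}"
        )
    model_dir = model_degs["direction"]
    treat_dir = treat_degs["direction"].loc[model_dir.index]
    category = pd.Series("not_reversed", index=model_dir.index)
    category[model_dir == "ns"] = "unaffected"
    rev = (model_dir != "ns") & (treat_dir == model_dir.map(_OPPOSITE))
    category[rev] = "reversed"
    return pd.DataFrame(
        {
            "model_direction": model_dir,
            "treatment_direction": treat_dir,
            "category": category,
        }
    )


def herb_pair_core_genes(minus_a_degs: pd.DataFrame, minus_b_degs: pd.DataFrame) -> set[str]:
    """Genes dysregulated in both deleted-herb-versus-full-formula screens.

    The intersection of the two dysregulated (up ∪ down) sets: the genes
    whose response to the formula depends on either herb of the pair.
    Symmetric in its arguments.
    """
    def dysregulated(t: pd.DataFrame) -> set[str]:
        return set(t.index[t["direction"].isin(["up", "down"])])

    return dysregulated(minus_a_degs) & dysregulated(minus_b_degs)


def merge_known_genes(sources: list[tuple[str, list[str]]]) -> KnownGeneSet:
    """Union of labelled known-gene lists with per-gene source provenance.

    Gene ids are expected case-normalised by the caller; order of the
    merged set is deterministic (sorted).
    """
    if not sources:
        raise ValueError("no known-gene sources given")
    source_of: dict[str, list[str]] = {}
    for label, genes in sources:
        for g in genes:
            tags = source_of.setdefault(g, [])
            if label not in tags:
                tags.append(label)
    return KnownGeneSet(gene_ids=set(source_of), source_of=source_of)


def load_known_gene_list(path) -> tuple[str, list[str]]:
    """Read a plain-text gene list: optional ``# label`` header, one gene
    id per line.  Returns (label, genes); the filename stem is the label
    when no header is present."""
    label = None
    genes: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if label is None:
                    label = line.lstrip("#").strip()
                continue
            genes.append(line)
    if label is None:
        import os

        label = os.path.splitext(os.path.basename(path))[0]
    return label, genes


def builtin_known_gene_sources() -> list[tuple[str, list[str]]]:
    """The packaged known goiter-gene lists.

    Two public-database exports ship with the package: the FDA-approved
    goiter drug targets from DrugBank (TPO, THRA, THRB) and the KEGG
    congenital-hypothyroidism/goiter disease genes (entry H00251).  Their
    union after de-duplication is the ten known goiter-related genes used
    by the comparative analyses.
    """
    out = []
    for fname in ("known_goiter_genes_drugbank.txt", "known_goiter_genes_kegg.txt"):
        ref = resources.files("netpharm.data").joinpath(fname)
        with resources.as_file(ref) as path:
            out.append(load_known_gene_list(path))
    return out
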