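"""Readers and writers for the pipeline's plain-text dialects.

All tables are TSV with a header row.  Fingerprints are hex-encoded
bitstrings (bit i = bit ``7 - i % 8`` of byte ``i // 8``, i.e. big-endian
within bytes).  Pathways use the GMT dialect: id, description, then member
genes, tab-separated.  A minimal GEO series-matrix reader is provided for
applying the expression stage to a deposited accession export.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .comparative import KnownGeneSet
from .enrichment import PathwayCollection
from .expression import ExpressionMatrix

__all__ = [
    "write_expression",
    "read_expression",
    "write_edges",
    "read_edges",
    "write_gmt",
    "read_gmt",
    "write_fingerprints",
    "read_fingerprints",
    "write_reference_drugs",
    "read_reference_drugs",
    "write_deg_table",
    "read_deg_table",
    "write_known_genes",
    "write_ground_truth",
    "read_ground_truth",
    "read_series_matrix",
    "bits_to_hex",
    "hex_to_bits",
]


# -- expression ---------------------------------------------------------------

def write_expression(expr: ExpressionMatrix, values_path, arm_map_path) -> None:
    """Expression TSV (rows=genes, columns=samples) + two-column arm map."""
    expr.values.to_csv(values_path, sep="\t", index_label="gene_id")
    pd.DataFrame(
        {"sample_id": expr.sample_ids, "arm": [expr.arm_of[s] for s in expr.sample_ids]}
    ).to_csv(arm_map_path, sep="\t", index=False)


def read_expression(values_path, arm_map_path) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="gene_id")
    arm_map = pd.read_csv(arm_map_path, sep="\t")
    arm_of = pd.Series(arm_map["arm"].to_numpy(), index=arm_map["sample_id"])
    return ExpressionMatrix(values=values, arm_of=arm_of)


# -- edge tables --------------------------------------------------------------

def write_edges(edges: pd.DataFrame, path) -> None:
    edges[["gene_a", "gene_b", "combined_score"]].to_csv(path, sep="\t", index=False)


def read_edges(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})


def write_network(net, edges_path, nodes_path=None) -> None:
    """Network as an edge TSV plus optional node-attribute TSV."""
    rows = [
        (u, v, d.get("combined_score", 1.0)) for u, v, d in net.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "combined_score"]).to_csv(
        edges_path, sep="\t", index=False
    )
    if nodes_path is not None:
        node_rows = [
            (n, ";".join(net.nodes[n].get("provenance", ()))) for n in net.nodes
        ]
        pd.DataFrame(node_rows, columns=["gene_id", "provenance"]).to_csv(
            nodes_path, sep="\t", index=False
        )


# -- pathways (GMT) -----------------------------------------------------------

def write_gmt(collection: PathwayCollection, path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(collection.pathways):
            name, genes = collection.pathways[pid]
            fh.write("\t".join([pid, name, *sorted(genes)]) + "\n")


def read_gmt(path, universe=None) -> PathwayCollection:
    pathways = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            pathways[parts[0]] = (parts[1], frozenset(parts[2:]))
    return PathwayCollection(pathways=pathways, universe=universe)


# -- fingerprints -------------------------------------------------------------

def bits_to_hex(bits: np.ndarray) -> str:
    return np.packbits(np.asarray(bits, dtype=np.uint8)).tobytes().hex()


def hex_to_bits(hexstr: str, n_bits: int) -> np.ndarray:
    return np.unpackbits(np.frombuffer(bytes.fromhex(hexstr), dtype=np.uint8))[
        :n_bits
    ].astype(bool)


def write_fingerprints(fingerprints: pd.DataFrame, path) -> None:
    out = fingerprints.copy()
    out["n_bits"] = [b.size for b in out["bits"]]
    out["bits"] = [bits_to_hex(b) for b in out["bits"]]
    out[["compound_id", "herb_id", "n_bits", "bits"]].to_csv(path, sep="\t", index=False)


def read_fingerprints(path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t")
    raw["bits"] = [hex_to_bits(h, n) for h, n in zip(raw["bits"], raw["n_bits"])]
    return raw[["compound_id", "herb_id", "bits"]]


def write_reference_drugs(reference: pd.DataFrame, path) -> None:
    out = reference.copy()
    out["n_bits"] = [b.size for b in out["bits"]]
    out["bits"] = [bits_to_hex(b) for b in out["bits"]]
    out["targets"] = [";".join(t) for t in out["targets"]]
    out[["drug_id", "n_bits", "bits", "targets"]].to_csv(path, sep="\t", index=False)


def read_reference_drugs(path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t")
    raw["bits"] = [hex_to_bits(h, n) for h, n in zip(raw["bits"], raw["n_bits"])]
    raw["targets"] = [tuple(t.split(";")) if t else () for t in raw["targets"].fillna("")]
    return raw[["drug_id", "bits", "targets"]]


# -- DEG tables ---------------------------------------------------------------

def write_deg_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="gene_id")


def read_deg_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


# -- known genes / ground truth ----------------------------------------------

def write_known_genes(label: str, genes, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {label}\n")
        for g in genes:
            fh.write(f"{g}\n")


def write_known_gene_set(kg: KnownGeneSet, path) -> None:
    rows = [(g, ";".join(kg.source_of[g])) for g in sorted(kg.gene_ids)]
    pd.DataFrame(rows, columns=["gene_id", "sources"]).to_csv(path, sep="\t", index=False)


def write_ground_truth(truth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_jsonable(), indent=2) + "\n")


def read_ground_truth(path) -> dict:
    return json.loads(Path(path).read_text())


# -- GEO series matrix --------------------------------------------------------

def read_series_matrix(path, arm_of: dict[str, str]) -> ExpressionMatrix:
    """Read the data block of a GEO series-matrix text export.

    Parses the ``!series_matrix_table_begin`` … ``_end`` block (ID_REF
    rows × GSM columns).  ``arm_of`` maps each GSM sample id to an arm
    label; samples absent from the map are dropped, so a five-arm design
    can be analysed one contrast at a time.  Values are assumed already
    log2-scale, matching the screening conventions.
    """
    lines = Path(path).read_text().splitlines()
    try:
        start = next(
            i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_begin")
        )
        end = next(
            i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_end")
        )
    except StopIteration:
        raise ValueError("no series-matrix table block found") from None
    block = lines[start + 1 : end]
    header = [c.strip('"') for c in block[0].split("\t")]
    rows = []
    for line in block[1:]:
        parts = line.split("\t")
        rows.append([parts[0].strip('"')] + [float(x) for x in parts[1:]])
    df = pd.DataFrame(rows, columns=header).set_index(header[0])
    df.index.name = "gene_id"
    keep = [c for c in df.columns if c in arm_of]
    if not keep:
        raise ValueError("no series-matrix samples present in the arm map")
    return ExpressionMatrix(values=df[keep], arm_of={s: arm_of[s] for s in keep})
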