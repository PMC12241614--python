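"""Readers and writers for the pipeline's on-disk formats.

All formats are plain text: TSV matrices/edge lists, BED-like motif hit
tables, GMT gene set collections and JSON for records. Expression matrices
are genes x samples with a header row of sample ids and the gene id as the
first column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .drug_matching import DrugSignature
from .priors import MotifPrior, PPIPrior

__all__ = [
    "read_expression",
    "write_expression",
    "read_covariates",
    "write_covariates",
    "read_annotations",
    "write_annotations",
    "read_motif_hits",
    "write_motif_hits",
    "read_ppi_edges",
    "write_ppi_edges",
    "read_gmt",
    "write_gmt",
    "write_prior_edges",
    "read_prior_edges",
    "read_drug_library",
    "write_drug_library",
    "write_json",
    "read_json",
]


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_covariates(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_covariates(cov: pd.DataFrame, path) -> None:
    cov.to_csv(path, sep="\t", index_label="sample")


def read_annotations(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype={"gene_id": str, "chromosome": str, "strand": str}
    )


def write_annotations(annot: pd.DataFrame, path) -> None:
    annot.to_csv(path, sep="\t", index=False)


def read_motif_hits(path) -> pd.DataFrame:
    """BED-like hit table: chrom, start, end, tf_id, p_value (1-based inclusive)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chromosome", "start", "end", "tf_id", "p_value"],
    )
    return df[["tf_id", "chromosome", "start", "end", "p_value"]]


def write_motif_hits(hits: pd.DataFrame, path) -> None:
    hits[["chromosome", "start", "end", "tf_id", "p_value"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_ppi_edges(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=["tf_a", "tf_b", "score"])


def write_ppi_edges(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", header=False, index=False)


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def write_prior_edges(prior: MotifPrior, path) -> None:
    prior.to_edge_list().to_csv(path, sep="\t", index=False)


def read_prior_edges(path, tfs=None, genes=None) -> MotifPrior:
    df = pd.read_csv(path, sep="\t")
    tfs = sorted(df["tf"].unique()) if tfs is None else list(tfs)
    genes = sorted(df["gene"].unique()) if genes is None else list(genes)
    ti = {t: i for i, t in enumerate(tfs)}
    gi = {g: j for j, g in enumerate(genes)}
    edges = np.zeros((len(tfs), len(genes)))
    for t, g, w in zip(df["tf"], df["gene"], df["weight"]):
        edges[ti[t], gi[g]] = 1.0 if w != 0 else 0.0
    return MotifPrior(tfs=tfs, genes=genes, edges=edges)


def read_drug_library(path) -> list[DrugSignature]:
    """Library TSV: drug, direction (up/down), gene — one gene per row."""
    df = pd.read_csv(path, sep="\t", header=None, names=["drug", "direction", "gene"])
    sigs = []
    for drug, chunk in df.groupby("drug", sort=False):
        sigs.append(
            DrugSignature(
                drug_id=str(drug),
                up=set(chunk.loc[chunk["direction"] == "up", "gene"]),
                down=set(chunk.loc[chunk["direction"] == "down", "gene"]),
            )
        )
    return sigs


def write_drug_library(library: list[DrugSignature], path) -> None:
    with open(path, "w") as fh:
        for sig in library:
            for g in sorted(sig.up):
                fh.write(f"{sig.drug_id}\tup\t{g}\n")
            for g in sorted(sig.down):
                fh.write(f"{sig.drug_id}\tdown\t{g}\n")


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, type):  # e.g. a dtype class in a config block
            return o.__name__
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=1, default=default))


def read_json(path):
    return json.loads(Path(path).read_text())
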