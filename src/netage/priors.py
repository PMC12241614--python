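"""Structural priors for regulatory-network inference.

Builds the three inputs PANDA reconciles: a binary TF x gene motif prior
(does a TF's binding motif occur in a gene's promoter window?), a symmetric
TF x TF protein-protein-interaction prior on [0, 1], and a filtered
expression matrix. Priors are made sex-specific by zeroing edges incident
to Y-chromosome genes in the female prior, so the male and female networks
share an identical edge universe and can be compared statistically.

Conventions
-----------
Genomic coordinates are 1-based inclusive (annotation-table style); overlap
means at least one shared base. The promoter window is defined relative to
the direction of transcription: ``upstream`` bases before the TSS and
``downstream`` bases after it, so the window is mirrored on the minus
strand. Expression matrices are genes x samples DataFrames; missing values
(``NaN``) are allowed and mean "not measured in this sample".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MotifPrior",
    "PPIPrior",
    "build_motif_prior",
    "make_sex_specific_prior",
    "build_ppi_prior",
    "preprocess_expression",
]


@dataclass
class MotifPrior:
    """Binary bipartite TF -> gene prior.

    ``edges[i, j] == 1`` iff TF ``tfs[i]`` has a significant motif hit in
    the promoter window of ``genes[j]`` (possibly zeroed afterwards for
    sex-specific priors).
    """

    tfs: list[str]
    genes: list[str]
    edges: np.ndarray

    def __post_init__(self) -> None:
        self.tfs = list(self.tfs)
        self.genes = list(self.genes)
        self.edges = np.asarray(self.edges, dtype=float)
        if self.edges.shape != (len(self.tfs), len(self.genes)):
            raise ValueError(
                f"edge matrix shape {self.edges.shape} does not match "
                f"{len(self.tfs)} TFs x {len(self.genes)} genes"
            )
        if not np.isin(self.edges, (0.0, 1.0)).all():
            raise ValueError("motif prior entries must be 0 or 1")

    @property
    def n_edges(self) -> int:
        return int(self.edges.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, index=self.tfs, columns=self.genes)

    def to_edge_list(self) -> pd.DataFrame:
        """Sparse representation: one row per nonzero edge (tf, gene, weight)."""
        ti, gi = np.nonzero(self.edges)
        return pd.DataFrame(
            {
                "tf": [self.tfs[i] for i in ti],
                "gene": [self.genes[j] for j in gi],
                "weight": self.edges[ti, gi],
            }
        )


@dataclass
class PPIPrior:
    """Symmetric TF x TF interaction-confidence prior in [0, 1], unit diagonal."""

    tfs: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.tfs = list(self.tfs)
        self.scores = np.asarray(self.scores, dtype=float)
        n = len(self.tfs)
        if self.scores.shape != (n, n):
            raise ValueError(f"score matrix shape {self.scores.shape} != ({n}, {n})")
        if not np.allclose(self.scores, self.scores.T):
            raise ValueError("PPI prior must be symmetric")
        if not np.allclose(np.diag(self.scores), 1.0):
            raise ValueError("PPI prior diagonal must be 1")
        if self.scores.min() < 0 or self.scores.max() > 1:
            raise ValueError("PPI prior entries must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.tfs, columns=self.tfs)


def _validate_annotations(annotations: pd.DataFrame) -> pd.DataFrame:
    required = {"gene_id", "chromosome", "strand", "tss"}
    missing = required - set(annotations.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    if annotations["gene_id"].duplicated().any():
        dup = annotations.loc[annotations["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id in annotations: {dup!r}")
    bad = ~annotations["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError("strand must be '+' or '-'")
    if (annotations["tss"] < 1).any():
        raise ValueError("tss coordinates must be >= 1")
    return annotations


def promoter_window(
    tss: int | np.ndarray, strand: str | np.ndarray, upstream: int, downstream: int
) -> tuple[np.ndarray, np.ndarray]:
    """1-based inclusive promoter interval around a TSS, strand-aware.

    On the plus strand the window is ``[tss - upstream, tss + downstream]``;
    on the minus strand transcription runs right-to-left, so it mirrors to
    ``[tss - downstream, tss + upstream]``.
    """
    tss = np.asarray(tss)
    plus = np.asarray(strand) == "+"
    start = np.where(plus, tss - upstream, tss - downstream)
    end = np.where(plus, tss + downstream, tss + upstream)
    return np.maximum(start, 1), end


def build_motif_prior(
    hits: pd.DataFrame,
    annotations: pd.DataFrame,
    upstream: int = 750,
    downstream: int = 250,
    p_threshold: float = 1e-5,
    tfs: list[str] | None = None,
) -> MotifPrior:
    """Build a binary motif prior from motif-hit intervals and gene annotations.

    An edge (tf, gene) is set iff some hit of the TF with
    ``p_value < p_threshold`` overlaps the gene's promoter window
    (default [-750, +250] bases around the TSS, strand-mirrored) by at least
    one base, hit and gene lying on the same chromosome.

    Parameters
    ----------
    hits
        DataFrame with columns ``tf_id, chromosome, start, end, p_value``
        (1-based inclusive intervals).
    annotations
        DataFrame with columns ``gene_id, chromosome, strand, tss``.
    tfs
        Optional explicit TF universe (rows); defaults to the TFs present
        in ``hits``, sorted.

    Hits on chromosomes absent from the annotation table are ignored; a
    single warning reports how many were dropped.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be >= 0")
    annotations = _validate_annotations(annotations)
    hits = hits.copy()
    if (hits["start"] > hits["end"]).any():
        raise ValueError("motif hit with start > end")

    if tfs is None:
        tfs = sorted(hits["tf_id"].unique())
    genes = list(annotations["gene_id"])
    tf_index = {t: i for i, t in enumerate(tfs)}
    edges = np.zeros((len(tfs), len(genes)), dtype=float)

    known_chroms = set(annotations["chromosome"])
    unknown = ~hits["chromosome"].isin(known_chroms)
    if unknown.any():
        warnings.warn(
            f"{int(unknown.sum())} motif hits on chromosomes absent from the "
            "annotation table were ignored",
            stacklevel=2,
        )
        hits = hits.loc[~unknown]
    hits = hits.loc[hits["p_value"] < p_threshold]
    hits = hits.loc[hits["tf_id"].isin(tf_index)]

    win_start, win_end = promoter_window(
        annotations["tss"].to_numpy(),
        annotations["strand"].to_numpy(),
        upstream,
        downstream,
    )
    gene_chrom = annotations["chromosome"].to_numpy()

    # group hits by chromosome; intervals overlap iff start <= win_end and end >= win_start
    for chrom, chunk in hits.groupby("chromosome", sort=False):
        on_chrom = np.nonzero(gene_chrom == chrom)[0]
        if on_chrom.size == 0:
            continue
        ws, we = win_start[on_chrom], win_end[on_chrom]
        hs = chunk["start"].to_numpy()[:, None]
        he = chunk["end"].to_numpy()[:, None]
        overlap = (hs <= we[None, :]) & (he >= ws[None, :])
        rows = chunk["tf_id"].map(tf_index).to_numpy()
        for k in range(len(chunk)):
            cols = on_chrom[overlap[k]]
            edges[rows[k], cols] = 1.0
    return MotifPrior(tfs=tfs, genes=genes, edges=edges)


def chry_genes(annotations: pd.DataFrame, genes: list[str] | None = None) -> list[str]:
    """Gene ids annotated on the Y chromosome (accepts 'Y' or 'chrY')."""
    mask = annotations["chromosome"].isin(["Y", "chrY"])
    ids = list(annotations.loc[mask, "gene_id"])
    if genes is not None:
        keep = set(genes)
        ids = [g for g in ids if g in keep]
    return ids


def make_sex_specific_prior(
    prior: MotifPrior, sex: str, annotations: pd.DataFrame
) -> MotifPrior:
    """Sex-specific motif prior: the female prior zeroes chrY gene columns.

    Female samples carry no Y chromosome, so every edge into a chrY gene is
    downweighed to zero; the male prior is returned unchanged. Keeping the
    chrY columns (as zeros) preserves an identical edge universe across the
    sexes.
    """
    if sex not in ("female", "male"):
        raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")
    annotations = _validate_annotations(annotations)
    covered = set(annotations["gene_id"])
    absent = [g for g in prior.genes if g not in covered]
    if absent:
        raise ValueError(f"annotations do not cover prior genes, e.g. {absent[0]!r}")
    if sex == "male":
        return MotifPrior(tfs=prior.tfs, genes=prior.genes, edges=prior.edges.copy())
    y = set(chry_genes(annotations, prior.genes))
    edges = prior.edges.copy()
    cols = [j for j, g in enumerate(prior.genes) if g in y]
    edges[:, cols] = 0.0
    return MotifPrior(tfs=prior.tfs, genes=prior.genes, edges=edges)


def build_ppi_prior(
    interactions: pd.DataFrame | list[tuple[str, str, float]],
    tfs: list[str],
) -> PPIPrior:
    """Symmetrized PPI prior from an edge list of 0-1000 confidence scores.

    Scores are divided by 1000; when both directions of a pair are given the
    larger survives (conservative symmetrization); every TF gets a
    self-interaction of 1; absent pairs are 0. Interactions naming TFs not in
    ``tfs`` are ignored.
    """
    if not isinstance(interactions, pd.DataFrame):
        interactions = pd.DataFrame(
            interactions, columns=["tf_a", "tf_b", "score"]
        )
    else:
        interactions = interactions.rename(
            columns=dict(zip(interactions.columns[:3], ["tf_a", "tf_b", "score"]))
        )
    scores = interactions["score"].to_numpy(dtype=float)
    if len(scores) and (scores.min() < 0 or scores.max() > 1000):
        raise ValueError("PPI scores must lie in [0, 1000]")

    n = len(tfs)
    idx = {t: i for i, t in enumerate(tfs)}
    mat = np.zeros((n, n), dtype=float)
    for a, b, s in zip(
        interactions["tf_a"], interactions["tf_b"], scores / 1000.0
    ):
        if a not in idx or b not in idx:
            continue
        i, j = idx[a], idx[b]
        mat[i, j] = max(mat[i, j], s)
        mat[j, i] = max(mat[j, i], s)
    np.fill_diagonal(mat, 1.0)
    return PPIPrior(tfs=list(tfs), scores=mat)


def preprocess_expression(
    raw: pd.DataFrame,
    covariates: pd.DataFrame,
    tpm_threshold: float = 1.0,
    sample_fraction: float = 0.10,
    prior_genes: list[str] | None = None,
    annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Filter a TPM expression matrix and mask chrY expression in females.

    A gene is dropped iff its value is below ``tpm_threshold`` in at least
    ``sample_fraction`` of the samples (count >= fraction * n_samples,
    missing values not counted as low). Surviving genes are intersected with
    ``prior_genes`` (order preserved); then, if ``annotations`` and a
    ``sex`` covariate column are given, chrY values of female samples are
    set to NaN — females carry no Y chromosome, so those measurements are
    treated as not applicable rather than zero.

    ``raw`` is genes x samples; ``covariates`` is indexed by sample id and
    must cover all samples.
    """
    missing_samples = [s for s in raw.columns if s not in covariates.index]
    if missing_samples:
        raise ValueError(
            f"covariates do not cover samples, e.g. {missing_samples[0]!r}"
        )
    n_samples = raw.shape[1]
    low = (raw < tpm_threshold).sum(axis=1)
    keep = low < sample_fraction * n_samples
    out = raw.loc[keep].copy()
    if prior_genes is not None:
        in_prior = set(prior_genes)
        out = out.loc[[g for g in out.index if g in in_prior]]
        if out.shape[0] == 0:
            raise ValueError("no genes survive intersection with the prior")
    if annotations is not None and "sex" in covariates.columns:
        y = [g for g in chry_genes(annotations) if g in out.index]
        females = covariates.index[covariates["sex"] == "female"]
        females = [s for s in females if s in out.columns]
        if y and len(females):
            out.loc[y, females] = np.nan
    return out
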