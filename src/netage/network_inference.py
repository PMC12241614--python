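"""PANDA aggregate-network inference and LIONESS single-sample networks.

PANDA reconciles three evidence channels — a binary motif prior (candidate
TF -> gene edges), a TF-TF protein-interaction prior (cooperativity) and a
gene-gene coexpression matrix (co-regulation) — by message passing. All
three are z-score normalized, then iteratively updated: each edge weight
moves toward the average of a *responsibility* (does the TF's interaction
profile agree with the edge pattern of the target gene?) and an
*availability* (does the gene's coexpression profile agree with the TF's
targeting pattern?), both measured with a continuous Tanimoto similarity.
The cooperativity and co-regulation matrices are in turn pulled toward the
Tanimoto self-similarity of the current edge matrix, so the three channels
converge on a consistent picture.

LIONESS reconstructs a network for each individual sample by linear
interpolation: if the aggregate network is, to first order, an average of
per-sample networks, then the network of sample ``q`` is
``N * (e_all - e_without_q) + e_without_q``.

Edge weights are z-like scores and may be negative; larger means more
evidence for the regulatory interaction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .priors import MotifPrior, PPIPrior

__all__ = [
    "PandaConfig",
    "AggregateNetwork",
    "SampleNetworkSet",
    "zscore_normalize",
    "coexpression",
    "tanimoto",
    "run_panda",
    "run_lioness",
    "run_lioness_by_sex",
]


@dataclass
class PandaConfig:
    """Message-passing hyperparameters.

    alpha
        Learning rate in (0, 1]: fraction of each update step applied.
    tolerance
        Convergence threshold on the mean absolute proposed edge change.
    max_iterations
        Hard cap on update iterations.
    strict_reference_mode
        If True (default), the diagonal of the cooperativity/co-regulation
        self-similarity updates is refreshed to
        ``offdiag_row_std * n * exp(2 * alpha * step)``, the convention of
        the published reference implementation; if False, the simplified
        ``offdiag_row_std * n`` refresh is used.
    dtype
        float64 (default) or float32; float32 roughly halves the runtime of
        large gene sets at negligible cost to downstream statistics.
    """

    alpha: float = 0.1
    tolerance: float = 1e-3
    max_iterations: int = 200
    strict_reference_mode: bool = True
    dtype: type = np.float64

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class AggregateNetwork:
    """PANDA output: TF x gene edge-weight matrix with convergence metadata."""

    tfs: list[str]
    genes: list[str]
    weights: np.ndarray
    iterations_run: int = 0
    converged: bool = False
    delta_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.tfs), len(self.genes)):
            raise ValueError("weight matrix shape does not match id lists")
        if not np.isfinite(self.weights).all():
            raise ValueError("network weights must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.tfs, columns=self.genes)


@dataclass
class SampleNetworkSet:
    """Per-sample TF x gene networks sharing one TF/gene ordering.

    ``weights`` has shape (n_samples, n_tfs, n_genes), one slice per sample
    in ``samples`` order.
    """

    tfs: list[str]
    genes: list[str]
    samples: list[str]
    weights: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = (len(self.samples), len(self.tfs), len(self.genes))
        if self.weights.shape != expected:
            raise ValueError(
                f"weights shape {self.weights.shape} != {expected}"
            )

    def network(self, sample: str) -> pd.DataFrame:
        q = self.samples.index(sample)
        return pd.DataFrame(self.weights[q], index=self.tfs, columns=self.genes)


def zscore_normalize(matrix: np.ndarray) -> np.ndarray:
    """Symmetric z-score conditioning used on every PANDA input.

    Each entry is the average (scaled by 1/sqrt(2)) of its z-score within
    its row and within its column. A row or column with zero variance
    cannot be standardized, so its term falls back to the z-score against
    the overall matrix mean/std; an all-constant matrix maps to zeros.
    """
    x = np.asarray(matrix)
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a matrix with at least 2 rows and 2 columns")
    mu, sd = x.mean(), x.std()
    row_mu, row_sd = x.mean(axis=1), x.std(axis=1)
    col_mu, col_sd = x.mean(axis=0), x.std(axis=0)
    # a std at rounding-noise level (e.g. a constant matrix shifted by a
    # constant) counts as zero, or the fallback would amplify noise
    tiny = 1e-12 * max(1.0, float(np.abs(x).max()))
    if sd <= tiny:
        return np.zeros_like(x)
    with np.errstate(divide="ignore", invalid="ignore"):
        zr = (x - row_mu[:, None]) / row_sd[:, None]
        zc = (x - col_mu[None, :]) / col_sd[None, :]
    fallback = (x - mu) / sd
    zr = np.where(row_sd[:, None] <= tiny, fallback, zr)
    zc = np.where(col_sd[None, :] <= tiny, fallback, zc)
    return (zr + zc) / math.sqrt(2.0)


def coexpression(expr: pd.DataFrame) -> np.ndarray:
    """Gene-gene Pearson correlation over samples, pairwise-complete.

    Missing values (e.g. chrY genes in female samples) are excluded pair by
    pair. Zero-variance genes get 0 off-diagonal; the diagonal is 1.
    """
    x = np.asarray(expr, dtype=float)
    if x.shape[1] < 3:
        raise ValueError("coexpression needs at least 3 samples")
    nan_rows = np.isnan(x).any(axis=1)
    if not nan_rows.any():
        with np.errstate(divide="ignore", invalid="ignore"):
            c = np.corrcoef(x)
    elif nan_rows.sum() <= 0.05 * x.shape[0]:
        # few genes with missing values (e.g. the chrY panel): fast dense
        # correlation on the complete rows, pairwise-complete patches for
        # the rest
        n_genes = x.shape[0]
        c = np.zeros((n_genes, n_genes))
        comp = ~nan_rows
        with np.errstate(divide="ignore", invalid="ignore"):
            c[np.ix_(comp, comp)] = np.corrcoef(x[comp])
            for i in np.nonzero(nan_rows)[0]:
                xi = x[i]
                ok = ~np.isnan(xi)
                xo = x[:, ok]
                row_ok = ~np.isnan(xo).any(axis=1)
                xi_o = xi[ok]
                xc = xo - np.nanmean(xo, axis=1, keepdims=True)
                xic = xi_o - xi_o.mean()
                num = np.nansum(xc * xic[None, :], axis=1)
                den = np.sqrt(np.nansum(xc * xc, axis=1) * (xic @ xic))
                row = num / den
                row[~row_ok] = np.nan  # both-missing pairs patched below
                c[i, :] = row
                c[:, i] = row
        # pairs of NaN-bearing genes: full pairwise-complete fallback
        bad = np.nonzero(nan_rows)[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            for a_idx, i in enumerate(bad):
                for j in bad[a_idx:]:
                    both = ~np.isnan(x[i]) & ~np.isnan(x[j])
                    if both.sum() >= 2:
                        xi = x[i, both] - x[i, both].mean()
                        xj = x[j, both] - x[j, both].mean()
                        d = math.sqrt((xi @ xi) * (xj @ xj))
                        v = (xi @ xj) / d if d > 0 else 0.0
                    else:
                        v = 0.0
                    c[i, j] = c[j, i] = v
    else:
        # masked moments via matrix products: for each gene pair, sums over
        # the samples observed in both.
        m = (~np.isnan(x)).astype(float)
        x0 = np.nan_to_num(x)
        n = m @ m.T
        sx = x0 @ m.T
        sxx = (x0 * x0) @ m.T
        sxy = x0 @ x0.T
        with np.errstate(divide="ignore", invalid="ignore"):
            cov = sxy / n - (sx / n) * (sx.T / n)
            var_x = sxx / n - (sx / n) ** 2
            c = cov / np.sqrt(var_x * var_x.T)
    c = np.nan_to_num(c, nan=0.0, posinf=0.0, neginf=0.0)
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)


def tanimoto(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Continuous Tanimoto similarity between rows of ``x`` and columns of ``y``.

    ``T(i, j) = a / sqrt(|x_i|^2 + |y_j|^2 - |a|)`` with ``a = x_i . y_j``;
    a pair of zero vectors maps to 0.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    a = x @ y
    # denom >= 0 mathematically (|a| <= (|x|^2 + |y|^2) / 2); guard the
    # zero-vector case and float32 rounding without a NaN-scrub pass
    b = np.abs(a)
    np.negative(b, out=b)
    b += (x * x).sum(axis=1)[:, None]
    b += (y * y).sum(axis=0)[None, :]
    np.maximum(b, np.finfo(a.dtype).tiny, out=b)
    np.sqrt(b, out=b)
    a /= b
    return a


def _refresh_diagonal(
    mat: np.ndarray, n: int, alpha: float, step: int, strict: bool
) -> None:
    """Replace the diagonal of a self-similarity update in place.

    Self-Tanimoto diagonals are identically 1 and would freeze the scale of
    the cooperativity/co-regulation channels; they are refreshed to the
    std of the off-diagonal row entries times ``n`` (reference mode further
    multiplies by ``exp(2 * alpha * step)``).
    """
    np.fill_diagonal(mat, 0.0)
    s = mat.sum(axis=1)
    ss = np.einsum("ij,ij->i", mat, mat)
    k = mat.shape[0] - 1
    mean = s / k
    var = np.maximum(ss / k - mean * mean, 0.0)
    fill = np.sqrt(var) * n
    if strict:
        fill = fill * math.exp(2.0 * alpha * step)
    np.fill_diagonal(mat, fill)


def run_panda(
    motif: MotifPrior | np.ndarray,
    ppi: PPIPrior | np.ndarray,
    coexpr: np.ndarray,
    config: PandaConfig | None = None,
) -> AggregateNetwork:
    """Message-passing reconciliation of motif, PPI and coexpression evidence.

    All three inputs are z-score normalized; then, per iteration, the edge
    matrix W (TF x gene) is moved a fraction ``alpha`` toward the average
    of the responsibility ``R = T(P, W)`` and availability ``A = T(W, C)``,
    and P (TF x TF) and C (gene x gene) are moved toward the Tanimoto
    self-similarity of W's rows/columns with refreshed diagonals. Iteration
    stops when the mean absolute proposed change in W drops below
    ``config.tolerance``.
    """
    config = config or PandaConfig()
    if isinstance(motif, MotifPrior):
        tfs, genes = motif.tfs, motif.genes
        motif_mat = motif.edges
    else:
        motif_mat = np.asarray(motif, dtype=float)
        tfs = [f"TF{i}" for i in range(motif_mat.shape[0])]
        genes = [f"G{j}" for j in range(motif_mat.shape[1])]
    ppi_mat = ppi.scores if isinstance(ppi, PPIPrior) else np.asarray(ppi, dtype=float)
    if isinstance(ppi, PPIPrior) and ppi.tfs != tfs:
        raise ValueError("PPI prior TF ordering does not match motif prior")
    coexpr = np.asarray(coexpr, dtype=float)
    n_tfs, n_genes = motif_mat.shape
    if ppi_mat.shape != (n_tfs, n_tfs):
        raise ValueError("PPI matrix shape does not match TF count")
    if coexpr.shape != (n_genes, n_genes):
        raise ValueError("coexpression shape does not match gene count")

    dt = config.dtype
    w = zscore_normalize(motif_mat.astype(dt, copy=False))
    p = zscore_normalize(ppi_mat.astype(dt, copy=False))
    c = zscore_normalize(coexpr.astype(dt, copy=False))
    alpha = dt(config.alpha)
    one_minus = dt(1.0 - config.alpha)
    half = dt(0.5)

    history: list[float] = []
    converged = False
    step = 0
    for step in range(config.max_iterations):
        resp = tanimoto(p, w)
        avail = tanimoto(w, c)
        proposed = half * (resp + avail)
        delta = float(np.abs(w - proposed).mean())
        if not math.isfinite(delta):
            raise FloatingPointError(
                f"non-finite update at iteration {step}"
            )
        history.append(delta)
        w = one_minus * w + alpha * proposed
        if delta < config.tolerance:
            converged = True
            step += 1
            break
        p_new = tanimoto(w, w.T)
        _refresh_diagonal(
            p_new, n_tfs, config.alpha, step, config.strict_reference_mode
        )
        p *= one_minus
        p_new *= alpha
        p += p_new
        c_new = tanimoto(w.T, w)
        _refresh_diagonal(
            c_new, n_genes, config.alpha, step, config.strict_reference_mode
        )
        c *= one_minus
        c_new *= alpha
        c += c_new
        step += 1
    return AggregateNetwork(
        tfs=list(tfs),
        genes=list(genes),
        weights=w.astype(np.float64),
        iterations_run=step,
        converged=converged,
        delta_history=history,
    )


def _panda_network_fn(
    motif: MotifPrior, ppi: PPIPrior, config: PandaConfig
) -> Callable[[pd.DataFrame], np.ndarray]:
    def fn(expr_subset: pd.DataFrame) -> np.ndarray:
        c = coexpression(expr_subset)
        return run_panda(motif, ppi, c, config).weights

    return fn


def run_lioness(
    expr: pd.DataFrame,
    motif: MotifPrior | None = None,
    ppi: PPIPrior | None = None,
    config: PandaConfig | None = None,
    network_fn: Callable[[pd.DataFrame], np.ndarray] | None = None,
) -> SampleNetworkSet:
    """Single-sample networks by leave-one-out linear interpolation.

    For each sample ``q`` of N, the aggregate network function is evaluated
    with and without the sample and the sample's own network estimated as
    ``N * (e_all - e_without_q) + e_without_q``. The default network
    function is PANDA on the Pearson coexpression of the sample subset with
    the shared motif and PPI priors; any function mapping an expression
    subset (genes x samples DataFrame) to a weight matrix may be supplied
    instead.
    """
    n = expr.shape[1]
    if n < 4:
        raise ValueError("LIONESS needs at least 4 samples")
    config = config or PandaConfig()
    if network_fn is None:
        if motif is None or ppi is None:
            raise ValueError("motif and ppi priors required for the PANDA network_fn")
        if list(expr.index) != list(motif.genes):
            expr = expr.loc[motif.genes]
        network_fn = _panda_network_fn(motif, ppi, config)
        tfs, genes = motif.tfs, motif.genes
    else:
        tfs = genes = None

    e_all = np.atleast_2d(np.asarray(network_fn(expr), dtype=float))
    if tfs is None:
        tfs = [f"TF{i}" for i in range(e_all.shape[0])]
        genes = (
            list(expr.index)
            if e_all.shape[1] == expr.shape[0]
            else [f"G{j}" for j in range(e_all.shape[1])]
        )
    samples = list(expr.columns)
    out = np.empty((n,) + e_all.shape, dtype=e_all.dtype)
    for q in range(n):
        subset = expr.drop(columns=samples[q])
        e_sub = np.atleast_2d(np.asarray(network_fn(subset), dtype=float))
        out[q] = n * (e_all - e_sub) + e_sub
    return SampleNetworkSet(
        tfs=list(tfs),
        genes=list(genes),
        samples=samples,
        weights=out,
        provenance={
            "n_samples": n,
            "config": None if config is None else vars(config).copy(),
        },
    )


def run_lioness_by_sex(
    expr: pd.DataFrame,
    covariates: pd.DataFrame,
    motif_by_sex: dict[str, MotifPrior],
    ppi: PPIPrior,
    config: PandaConfig | None = None,
) -> dict[str, SampleNetworkSet]:
    """Run LIONESS separately within each sex stratum.

    Networks are estimated per stratum with that stratum's sex-specific
    motif prior (female chrY columns zeroed), so coexpression is never
    pooled across sexes. The returned sets share identical TF and gene
    orderings, which downstream indegree concatenation asserts.
    """
    out: dict[str, SampleNetworkSet] = {}
    ref_tfs = ref_genes = None
    for sex, prior in motif_by_sex.items():
        samples = [
            s for s in expr.columns if covariates.loc[s, "sex"] == sex
        ]
        if len(samples) < 4:
            raise ValueError(f"stratum {sex!r} has fewer than 4 samples")
        nets = run_lioness(expr[samples], prior, ppi, config)
        nets.provenance["sex"] = sex
        if ref_tfs is None:
            ref_tfs, ref_genes = nets.tfs, nets.genes
        elif nets.tfs != ref_tfs or nets.genes != ref_genes:
            raise ValueError("sex strata disagree on TF/gene ordering")
        out[sex] = nets
    return out
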