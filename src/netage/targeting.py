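"""Differential TF-targeting statistics on single-sample networks.

The unit of analysis is the *targeting score* (indegree) of a gene in a
sample: the sum of all incoming edge weights from all TFs in that sample's
network. Age-related regulatory change is quantified by regressing each
gene's targeting score on age (plus covariates) across samples and ranking
genes by the t-statistic of the age coefficient. An empirical-Bayes
moderated t (limma-style variance shrinkage) is the default: per-gene
residual variances are shrunk toward a pooled prior estimated by fitting a
scaled-F distribution to the observed variances, stabilizing t-statistics
when residual degrees of freedom are modest.

The slope of the age coefficient is the change in indegree per year of
age; figure conventions sometimes label this quantity "logFC", but no log
transform is involved and it is stored here as ``slope``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .network_inference import SampleNetworkSet

__all__ = [
    "TargetingScores",
    "DiffTargetingResult",
    "Trajectory",
    "indegree",
    "concat_indegrees",
    "build_design",
    "fit_linear_models",
    "moderate_tstats",
    "select_age_genes",
    "rank_sum_compare",
    "aging_trajectory",
    "DifferentialTargetingModel",
]

#: reference levels used for dummy coding of the standard covariates,
#: so coefficient meaning is deterministic across runs.
REFERENCE_LEVELS = {
    "sex": "female",
    "smoking": "never",
    "disease": "healthy",
    "stage": "I",
}


def indegree(networks: SampleNetworkSet) -> pd.DataFrame:
    """Gene x sample targeting scores: per-sample sum of incoming edge weights."""
    if len(networks.samples) == 0:
        raise ValueError("empty network set")
    scores = networks.weights.sum(axis=1)  # (samples, genes)
    return pd.DataFrame(
        scores.T, index=networks.genes, columns=networks.samples
    )


def concat_indegrees(network_sets: dict[str, SampleNetworkSet]) -> pd.DataFrame:
    """Column-concatenate indegrees from stratified runs (e.g. per sex).

    Asserts all strata share one gene ordering; sample columns are the
    concatenation of the strata in dict order.
    """
    frames = []
    ref = None
    for nets in network_sets.values():
        d = indegree(nets)
        if ref is None:
            ref = list(d.index)
        elif list(d.index) != ref:
            raise ValueError("strata disagree on gene ordering")
        frames.append(d)
    return pd.concat(frames, axis=1)


def build_design(
    covariates: pd.DataFrame,
    terms: list[str],
    interaction: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Design matrix with intercept, dummy-coded categoricals and optional interaction.

    Numeric columns enter as-is; categoricals are reference-level dummy
    coded (reference per ``REFERENCE_LEVELS`` when declared, else the first
    sorted level). ``interaction=("age", "smoking")`` adds the product of
    the age column with each smoking dummy.
    """
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(covariates))}
    by_term: dict[str, list[str]] = {}
    for term in terms:
        v = covariates[term]
        if pd.api.types.is_numeric_dtype(v):
            cols[term] = v.to_numpy(dtype=float)
            by_term[term] = [term]
        else:
            levels = sorted(v.dropna().astype(str).unique())
            ref = REFERENCE_LEVELS.get(term, levels[0] if levels else None)
            by_term[term] = []
            for lev in levels:
                if lev == ref:
                    continue
                name = f"{term}[{lev}]"
                cols[name] = (v.astype(str) == lev).to_numpy(dtype=float)
                by_term[term].append(name)
    if interaction is not None:
        a, b = interaction
        for an in by_term[a]:
            for bn in by_term[b]:
                cols[f"{an}:{bn}"] = cols[an] * cols[bn]
    return pd.DataFrame(cols, index=covariates.index)


@dataclass
class DiffTargetingResult:
    """Per-gene statistics for one coefficient of the shared linear model."""

    genes: list[str]
    coefficient: str
    slope: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df_residual: np.ndarray
    residual_variance: np.ndarray
    stdunscaled: np.ndarray
    moderated_t: np.ndarray | None = None
    moderated_p: np.ndarray | None = None
    df_prior: float | None = None
    var_prior: float | None = None
    n_samples_used: int = 0

    def to_frame(self) -> pd.DataFrame:
        d = {
            "slope": self.slope,
            "t": self.t,
            "p": self.p,
            "df_residual": self.df_residual,
            "residual_variance": self.residual_variance,
        }
        if self.moderated_t is not None:
            d["moderated_t"] = self.moderated_t
            d["moderated_p"] = self.moderated_p
        return pd.DataFrame(d, index=pd.Index(self.genes, name="gene"))

    @property
    def best_t(self) -> np.ndarray:
        """Moderated t when available, ordinary t otherwise."""
        return self.t if self.moderated_t is None else self.moderated_t

    @property
    def best_p(self) -> np.ndarray:
        return self.p if self.moderated_p is None else self.moderated_p


def _ols_stats(
    x: np.ndarray, y: np.ndarray, j: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float]:
    """OLS of each row of y on shared design x; stats for coefficient j.

    Returns (beta_j, s2, t) arrays over rows plus (df, c_jj) where
    ``c_jj = [(X'X)^-1]_jj`` so SE = s * sqrt(c_jj).
    """
    n, k = x.shape
    df = n - k
    if df <= 0:
        raise ValueError("design has no residual degrees of freedom")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = y @ (xtx_inv @ x.T).T  # (genes, k)
    resid = y - beta @ x.T
    s2 = (resid * resid).sum(axis=1) / df
    c_jj = xtx_inv[j, j]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[:, j] / np.sqrt(s2 * c_jj)
    return beta[:, j], s2, t, float(df), float(c_jj)


def fit_linear_models(
    scores: pd.DataFrame,
    covariates: pd.DataFrame,
    terms: list[str] | None = None,
    coefficient: str = "age",
    interaction: tuple[str, str] | None = None,
) -> DiffTargetingResult:
    """Per-gene OLS of targeting scores on a shared covariate design.

    Samples with a missing value in any design column are dropped listwise;
    genes with missing responses (chrY genes in females) are fitted on
    their complete cases. The returned statistics concern one coefficient —
    by default ``age``; for an interaction model pass e.g.
    ``interaction=("age", "smoking")`` and ``coefficient="age:smoking[ever]"``.

    Two-sided p-values come from the t distribution on the residual
    degrees of freedom.
    """
    terms = terms if terms is not None else ["age"]
    covariates = covariates.loc[scores.columns]
    complete = covariates[terms].notna().all(axis=1)
    design = build_design(covariates.loc[complete], terms, interaction)
    y_all = scores.loc[:, complete.index[complete]]
    x = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        u, s, vt = np.linalg.svd(x)
        aliased = [
            design.columns[i]
            for i in np.nonzero(np.abs(vt[-1]) > 1e-8)[0]
        ]
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    if coefficient not in design.columns:
        raise KeyError(
            f"coefficient {coefficient!r} not in design columns {list(design.columns)}"
        )
    j = design.columns.get_loc(coefficient)

    genes = list(y_all.index)
    g = len(genes)
    slope = np.full(g, np.nan)
    s2 = np.full(g, np.nan)
    t = np.full(g, np.nan)
    dfres = np.full(g, np.nan)
    c_jj_arr = np.full(g, np.nan)

    y = y_all.to_numpy(dtype=float)
    nan_rows = np.isnan(y).any(axis=1)
    if (~nan_rows).any():
        b, v, tt, df, cjj = _ols_stats(x, y[~nan_rows], j)
        slope[~nan_rows], s2[~nan_rows], t[~nan_rows] = b, v, tt
        dfres[~nan_rows] = df
        c_jj_arr[~nan_rows] = cjj
    # genes with missing responses: group by missingness pattern so each
    # pattern costs one shared-design fit.
    if nan_rows.any():
        patterns: dict[bytes, list[int]] = {}
        masks = ~np.isnan(y[nan_rows])
        idx = np.nonzero(nan_rows)[0]
        for row, gi in zip(masks, idx):
            patterns.setdefault(row.tobytes(), []).append(gi)
        for key, gis in patterns.items():
            mask = np.frombuffer(key, dtype=bool)
            if mask.sum() <= x.shape[1]:
                continue  # not enough complete cases; stats stay NaN
            xm = x[mask]
            if np.linalg.matrix_rank(xm) < xm.shape[1]:
                continue
            b, v, tt, df, cjj = _ols_stats(xm, y[np.ix_(gis, np.nonzero(mask)[0])], j)
            slope[gis], s2[gis], t[gis] = b, v, tt
            dfres[gis] = df
            c_jj_arr[gis] = cjj

    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.t.sf(np.abs(t), dfres)
    return DiffTargetingResult(
        genes=genes,
        coefficient=coefficient,
        slope=slope,
        t=t,
        p=p,
        df_residual=dfres,
        residual_variance=s2,
        stdunscaled=np.sqrt(c_jj_arr),
        n_samples_used=int(complete.sum()),
    )


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif / y) < 1e-8:
            break
    return float(y)


def _fit_f_dist(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-match a scaled F distribution to sample variances.

    Under the hierarchical model s2_g ~ s0^2 * F(d_g, d0), log s2 has known
    mean/variance offsets given by digamma/trigamma; matching the empirical
    moments of log s2 yields the prior df ``d0`` and prior variance
    ``s0^2``. Returns ``(d0, s0sq)``; ``d0 = inf`` when the observed spread
    is no larger than expected from chi-square sampling alone.
    """
    ok = np.isfinite(s2) & (s2 > 0) & np.isfinite(df) & (df > 0)
    s2, df = s2[ok], df[ok]
    if s2.size < 2:
        raise ValueError("need at least 2 positive variances")
    z = np.log(s2)
    if np.ptp(z) == 0:
        # identical variances: shrinkage target is that common variance
        return np.inf, float(s2[0])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0).mean()
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(float(evar))
        s0sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0sq = float(np.exp(emean))
    return d0, s0sq


def moderate_tstats(result: DiffTargetingResult) -> DiffTargetingResult:
    """Empirical-Bayes moderated t-statistics (variance shrinkage).

    The posterior variance squeezes each gene's residual variance toward
    the fitted prior: ``s2_post = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g)``;
    the moderated t divides the slope by the posterior standard error and
    is referred to a t distribution on ``d0 + d_g`` degrees of freedom. If
    the prior cannot be estimated (degenerate variance spread) the ordinary
    statistics are returned unchanged with a warning.
    """
    ok = np.isfinite(result.residual_variance) & (result.df_residual > 0)
    if ok.sum() < 10:
        raise ValueError("need >= 10 genes with positive residual df")
    try:
        d0, s0sq = _fit_f_dist(
            result.residual_variance[ok], result.df_residual[ok]
        )
    except (ValueError, FloatingPointError):
        import warnings

        warnings.warn(
            "degenerate variance distribution; falling back to ordinary t",
            stacklevel=2,
        )
        return result
    s2 = result.residual_variance
    df = result.df_residual
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
        df_total = np.full_like(df, np.inf)
    else:
        s2_post = (d0 * s0sq + df * s2) / (d0 + df)
        df_total = d0 + df
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = result.slope / (np.sqrt(s2_post) * result.stdunscaled)
        p_mod = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    return DiffTargetingResult(
        genes=result.genes,
        coefficient=result.coefficient,
        slope=result.slope,
        t=result.t,
        p=result.p,
        df_residual=result.df_residual,
        residual_variance=result.residual_variance,
        stdunscaled=result.stdunscaled,
        moderated_t=t_mod,
        moderated_p=p_mod,
        df_prior=float(d0),
        var_prior=s0sq,
        n_samples_used=result.n_samples_used,
    )


def select_age_genes(
    result: DiffTargetingResult, p_threshold: float = 0.05
) -> tuple[list[str], list[str]]:
    """Split genes into increasingly/decreasingly targeted at ``p < threshold``.

    Uses the moderated p-values when present; the threshold is a strict
    inequality. Returns ``(up, down)`` — disjoint by the sign condition.
    """
    p = result.best_p
    up = [
        g
        for g, pv, b in zip(result.genes, p, result.slope)
        if np.isfinite(pv) and pv < p_threshold and b > 0
    ]
    down = [
        g
        for g, pv, b in zip(result.genes, p, result.slope)
        if np.isfinite(pv) and pv < p_threshold and b < 0
    ]
    return up, down


def rank_sum_compare(
    stats_a: np.ndarray, stats_b: np.ndarray, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) comparison of two statistic lists.

    Exact enumeration when both groups have <= 20 observations and no ties
    span the groups; otherwise the normal approximation with continuity
    correction and midrank tie handling. ``alternative`` refers to group A
    relative to group B. If every value is tied across both groups, p = 1.
    """
    a = np.asarray(stats_a, dtype=float)
    b = np.asarray(stats_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    alt = {"two-sided": "two-sided", "greater": "greater", "less": "less"}[
        alternative
    ]
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        return float(a.size * b.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = (
        "exact" if (a.size <= 20 and b.size <= 20 and not has_ties) else "asymptotic"
    )
    res = stats.mannwhitneyu(
        a, b, alternative=alt, method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


@dataclass
class Trajectory:
    """Age-binned targeting-score medians with per-subgroup fitted lines."""

    bins: pd.DataFrame  # columns: bin, midpoint, subgroup, median, n
    fits: pd.DataFrame  # index: subgroup; columns: slope, intercept, n_bins
    gene_set_size: int = 0

    def subgroup_slope(self, subgroup: str) -> float:
        return float(self.fits.loc[subgroup, "slope"])


def aging_trajectory(
    scores: pd.DataFrame,
    gene_set: list[str],
    covariates: pd.DataFrame,
    n_bins: int = 20,
    subgroup_col: str = "smoking",
) -> Trajectory:
    """Gene-set aging trajectory, stratified by smoking history.

    Each sample's score is the mean indegree over the gene set (NaNs
    ignored). Samples are split into ``n_bins`` consecutive age groups of
    equal size (quantile bins; remainder samples go to the earliest bins,
    ties broken by stable sample order). Within each bin the median score
    is computed per subgroup, and a least-squares line of median against
    bin age midpoint is fitted per subgroup. Empty bin x subgroup cells are
    omitted and recorded by their absence.
    """
    present = [g for g in gene_set if g in scores.index]
    if not present:
        raise ValueError("gene set does not intersect score genes")
    if scores.shape[1] < n_bins:
        raise ValueError(f"need at least {n_bins} samples")
    covariates = covariates.loc[scores.columns]
    per_sample = scores.loc[present].mean(axis=0, skipna=True)

    order = np.argsort(covariates["age"].to_numpy(), kind="stable")
    n = len(order)
    base, rem = divmod(n, n_bins)
    sizes = [base + (1 if i < rem else 0) for i in range(n_bins)]
    rows = []
    start = 0
    ages = covariates["age"].to_numpy()
    groups = covariates[subgroup_col].astype(str).to_numpy()
    for b, size in enumerate(sizes):
        members = order[start : start + size]
        start += size
        if size == 0:
            continue
        mid = (ages[members].min() + ages[members].max()) / 2.0
        for sub in np.unique(groups):
            sel = members[groups[members] == sub]
            if sel.size == 0:
                continue
            rows.append(
                {
                    "bin": b,
                    "midpoint": mid,
                    "subgroup": sub,
                    "median": float(np.median(per_sample.iloc[sel])),
                    "n": int(sel.size),
                }
            )
    bins = pd.DataFrame(rows)
    fits = {}
    for sub, chunk in bins.groupby("subgroup"):
        if len(chunk) >= 2 and chunk["midpoint"].nunique() > 1:
            sl, ic = np.polyfit(chunk["midpoint"], chunk["median"], 1)
        else:
            sl, ic = 0.0, float(chunk["median"].mean())
        fits[sub] = {"slope": float(sl), "intercept": float(ic), "n_bins": len(chunk)}
    return Trajectory(
        bins=bins,
        fits=pd.DataFrame(fits).T,
        gene_set_size=len(present),
    )


class DifferentialTargetingModel:
    """Covariate-adjusted differential-targeting model (Model/fit interface).

    Wraps :func:`fit_linear_models` + :func:`moderate_tstats` in a
    fit-style object::

        model = DifferentialTargetingModel(scores, covariates,
                                           terms=["age", "sex", "smoking"])
        res = model.fit()           # moderated by default
        res.to_frame().head()

    ``scores`` is genes x samples; ``covariates`` indexed by sample id.
    """

    def __init__(
        self,
        scores: pd.DataFrame,
        covariates: pd.DataFrame,
        terms: list[str] | None = None,
        coefficient: str = "age",
        interaction: tuple[str, str] | None = None,
    ):
        self.scores = scores
        self.covariates = covariates
        self.terms = terms if terms is not None else ["age"]
        self.coefficient = coefficient
        self.interaction = interaction

    def fit(self, moderated: bool = True) -> DiffTargetingResult:
        res = fit_linear_models(
            self.scores,
            self.covariates,
            terms=self.terms,
            coefficient=self.coefficient,
            interaction=self.interaction,
        )
        if moderated:
            res = moderate_tstats(res)
        return res
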