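"""Network-based aging signature: pathway scores -> LASSO-Cox -> survival.

Each candidate pathway is summarized per sample by the first principal
component of its member genes' targeting scores (the *pathway targeting
score*). A Cox proportional-hazards model with an L1 (LASSO) penalty is
then fitted on these scores, the penalty chosen by K-fold cross-validated
partial-likelihood deviance under the one-standard-error rule, and the
*aging signature* of a sample is the linear predictor of the final model —
a sparse linear combination of pathway targeting scores. The signature is
evaluated by a median split with Kaplan-Meier curves and a log-rank test,
and by adjusted (unpenalized) Cox models.

The partial likelihood uses the Breslow approximation for tied event
times throughout (an Efron variant is available for the unpenalized fit).
Coordinate-descent details follow the standard penalized-Cox scheme:
an outer quadratic approximation of the partial likelihood (diagonal
Hessian weights, working responses) with cyclic soft-threshold updates,
warm-started along a log-spaced penalty path from ``lambda_max`` (the
smallest penalty with an all-zero solution) downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "pathway_score",
    "pathway_score_matrix",
    "CoxResult",
    "cox_fit",
    "lasso_cox_solve",
    "lasso_cox_path",
    "AgingSignatureModel",
    "fit_lasso_cox",
    "PenalizedCoxSignature",
    "aging_signature",
    "SurvivalCurve",
    "km_logrank",
    "split_train_test",
]


# ---------------------------------------------------------------------------
# pathway targeting scores


def pathway_score(
    scores: pd.DataFrame, pathway: list[str]
) -> tuple[np.ndarray, int]:
    """Per-sample pathway targeting score: PC1 of member-gene indegrees.

    The samples x genes submatrix is gene-centered and projected onto its
    leading principal axis; the sign is oriented so the score correlates
    positively with the mean pathway indegree (orientation returned as
    +1/-1). A single-gene pathway degenerates to that gene's centered
    indegree.
    """
    present = [g for g in pathway if g in scores.index]
    if len(present) == 0:
        raise ValueError("no pathway genes present in the score matrix")
    if scores.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    sub = scores.loc[present].to_numpy(dtype=float).T  # samples x genes
    sub = sub - sub.mean(axis=0, keepdims=True)
    if len(present) == 1:
        return sub[:, 0], 1
    u, s, _ = np.linalg.svd(sub, full_matrices=False)
    proj = u[:, 0] * s[0]
    mean_indegree = sub.mean(axis=1)
    orient = 1
    if np.dot(proj, mean_indegree) < 0:
        proj, orient = -proj, -1
    return proj, orient


def pathway_score_matrix(
    scores: pd.DataFrame, gene_sets: dict[str, list[str]]
) -> pd.DataFrame:
    """Pathways x samples matrix of PC1 targeting scores (rows centered)."""
    rows = {}
    for name, genes in gene_sets.items():
        vec, _ = pathway_score(scores, genes)
        rows[name] = vec
    return pd.DataFrame(rows, index=scores.columns).T


# ---------------------------------------------------------------------------
# Breslow partial likelihood machinery


class _CoxData:
    """Time-sorted survival data with tie-group bookkeeping."""

    def __init__(self, x: np.ndarray, time: np.ndarray, event: np.ndarray):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[0] != len(time):
            x = x.T
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=float)
        if (time <= 0).any():
            raise ValueError("survival times must be positive")
        if not np.isin(event, (0.0, 1.0)).all():
            raise ValueError("event indicator must be 0/1")
        order = np.argsort(time, kind="stable")
        self.x = x[order]
        self.time = time[order]
        self.event = event[order]
        self.order = order
        self.n, self.p = self.x.shape
        # contiguous groups of tied times (ascending)
        uniq, inverse = np.unique(self.time, return_inverse=True)
        self.group = inverse
        self.n_groups = uniq.size
        self.group_first = np.searchsorted(self.time, uniq, side="left")
        self.d_group = np.bincount(inverse, weights=self.event, minlength=uniq.size)

    def loglik_mu_w(self, eta: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        """Breslow log partial likelihood, martingale means mu, diagonal weights w.

        ``mu_i = exp(eta_i) * H(t_i)`` with ``H`` the Breslow cumulative
        hazard; the score with respect to eta is ``event - mu``.
        """
        eta = eta - eta.max()  # overflow guard; PL invariant to eta shifts
        ex = np.exp(eta)
        rev = np.cumsum(ex[::-1])[::-1]
        s0_group = rev[self.group_first]
        with np.errstate(divide="ignore"):
            c1 = np.where(s0_group > 0, self.d_group / s0_group, 0.0)
            c2 = np.where(s0_group > 0, self.d_group / s0_group**2, 0.0)
        h1 = np.cumsum(c1)[self.group]
        h2 = np.cumsum(c2)[self.group]
        mu = ex * h1
        w = np.maximum(mu - ex * ex * h2, 0.0)
        ll = float((self.event * eta).sum() - (self.d_group * np.log(s0_group)).sum())
        return ll, mu, w

    def loglik(self, beta: np.ndarray) -> float:
        return self.loglik_mu_w(self.x @ beta)[0]

    def gradient_information(
        self, beta: np.ndarray, efron: bool = False
    ) -> tuple[float, np.ndarray, np.ndarray]:
        """Log PL, gradient and observed information for Newton-Raphson."""
        eta = self.x @ beta
        eta = eta - eta.max()
        ex = np.exp(eta)
        exx = ex[:, None] * self.x
        rev0 = np.cumsum(ex[::-1])[::-1]
        rev1 = np.cumsum(exx[::-1], axis=0)[::-1]
        outer = exx[:, :, None] * self.x[:, None, :]
        rev2 = np.cumsum(outer[::-1], axis=0)[::-1]
        ll = 0.0
        grad = np.zeros(self.p)
        info = np.zeros((self.p, self.p))
        for g in range(self.n_groups):
            d = self.d_group[g]
            if d == 0:
                continue
            f = self.group_first[g]
            members = np.nonzero((self.group == g) & (self.event == 1))[0]
            xsum = self.x[members].sum(axis=0)
            if not efron:
                s0, s1, s2 = rev0[f], rev1[f], rev2[f]
                ll += eta[members].sum() - d * np.log(s0)
                grad += xsum - d * s1 / s0
                info += d * (s2 / s0 - np.outer(s1 / s0, s1 / s0))
            else:
                # Efron: tied events progressively removed from the risk set
                e0 = ex[members].sum()
                e1 = exx[members].sum(axis=0)
                e2 = outer[members].sum(axis=0)
                ll += eta[members].sum()
                for r in range(int(d)):
                    frac = r / d
                    s0 = rev0[f] - frac * e0
                    s1 = rev1[f] - frac * e1
                    s2 = rev2[f] - frac * e2
                    ll -= np.log(s0)
                    grad -= s1 / s0
                    info += s2 / s0 - np.outer(s1 / s0, s1 / s0)
                grad += xsum
        return float(ll), grad, info


@dataclass
class CoxResult:
    """Unpenalized Cox fit: coefficients, SEs, Wald tests, diagnostics."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    n: int
    n_events: int
    converged: bool
    warnings: list[str] = field(default_factory=list)

    @property
    def z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.coef / self.se

    @property
    def p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "HR": self.hazard_ratios(),
                "se": self.se,
                "z": self.z,
                "p": self.p,
            },
            index=self.names,
        )


def cox_fit(
    x: pd.DataFrame | np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    ties: str = "breslow",
    max_iter: int = 100,
    tol: float = 1e-10,
) -> CoxResult:
    """Unpenalized Cox proportional-hazards fit by Newton-Raphson.

    Breslow tie handling by default (``ties='efron'`` available). Monotone
    likelihood (perfect separation) is flagged with a warning and the
    last iterate reported rather than raised.
    """
    if isinstance(x, pd.DataFrame):
        names = list(x.columns)
        xm = x.to_numpy(dtype=float)
    else:
        xm = np.atleast_2d(np.asarray(x, dtype=float))
        if xm.shape[0] == 1 and len(time) > 1:
            xm = xm.T
        names = [f"x{j}" for j in range(xm.shape[1])]
    event = np.asarray(event, dtype=float)
    if event.sum() < 1:
        raise ValueError("no events in the data")
    data = _CoxData(xm, time, event)
    if np.linalg.matrix_rank(data.x - data.x.mean(0)) < data.p:
        raise ValueError("design matrix is rank deficient")
    efron = ties == "efron"
    beta = np.zeros(data.p)
    warnings_: list[str] = []
    converged = False
    ll_old = -np.inf
    info = np.eye(data.p)
    for _ in range(max_iter):
        ll, grad, info = data.gradient_information(beta, efron=efron)
        if np.abs(grad).max() < tol * (1 + abs(ll)):
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            warnings_.append("singular information matrix")
            break
        # step halving keeps the likelihood nondecreasing
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            if data.loglik(cand) >= ll - 1e-12:
                break
            factor /= 2.0
        beta = beta + factor * step
        if np.abs(beta).max() > 50:
            warnings_.append(
                "monotone likelihood suspected (possible perfect separation)"
            )
            break
        ll_old = ll
    ll, grad, info = data.gradient_information(beta, efron=efron)
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(data.p, np.nan)
    return CoxResult(
        names=names,
        coef=beta,
        se=se,
        loglik=ll,
        n=data.n,
        n_events=int(event.sum()),
        converged=converged,
        warnings=warnings_,
    )


# ---------------------------------------------------------------------------
# L1-penalized Cox by cyclic coordinate descent


def _soft(z: float, lam: float) -> float:
    if z > lam:
        return z - lam
    if z < -lam:
        return z + lam
    return 0.0


def _cd_solve(
    data: _CoxData,
    lam: float,
    beta0: np.ndarray,
    max_outer: int = 100,
    tol: float = 1e-7,
) -> np.ndarray:
    """Solve max (1/n) logPL(beta) - lam * ||beta||_1 from a warm start."""
    n, p = data.n, data.p
    beta = beta0.copy()
    x = data.x
    for outer in range(max_outer):
        eta = x @ beta
        ll, mu, w = data.loglik_mu_w(eta)
        w = np.maximum(w, 1e-10)
        z = eta + (data.event - mu) / w
        r = z - eta  # working residual
        nu = (w[:, None] * x * x).sum(axis=0) / n
        wx = w[:, None] * x

        def sweep(idxs) -> float:
            max_delta = 0.0
            for j in idxs:
                bj = beta[j]
                rho = wx[:, j] @ r / n + nu[j] * bj
                new = _soft(rho, lam) / nu[j] if nu[j] > 0 else 0.0
                if new != bj:
                    np.subtract(r, (new - bj) * x[:, j], out=r)
                    beta[j] = new
                    max_delta = max(max_delta, abs(new - bj))
            return max_delta

        # active-set strategy: full sweeps only to admit new coordinates
        for _ in range(100):
            if sweep(range(p)) < tol:
                break
            active = np.nonzero(beta)[0]
            for _ in range(1000):
                if sweep(active) < tol:
                    break
        if np.abs(x @ beta - eta).max() < tol * (1.0 + np.abs(eta).max()):
            return beta
    if np.abs(beta).max() > 100:
        raise FloatingPointError(f"coordinate descent diverged at lambda={lam:g}")
    return beta


def lasso_lambda_max(x: np.ndarray, time, event) -> float:
    """Smallest penalty at which the LASSO-Cox solution is identically zero."""
    data = _CoxData(x, time, event)
    _, mu, _ = data.loglik_mu_w(np.zeros(data.n))
    grad = data.x.T @ (data.event - mu) / data.n
    # relative epsilon keeps the KKT boundary case at exactly zero under
    # floating-point rounding
    return float(np.abs(grad).max() * (1.0 + 1e-10))


def lasso_cox_solve(
    x: np.ndarray,
    time,
    event,
    lam: float,
    beta0: np.ndarray | None = None,
    tol: float = 1e-9,
) -> np.ndarray:
    """L1-penalized Breslow-Cox coefficients at a single penalty value.

    ``lam = 0`` gives the unpenalized maximum partial-likelihood solution
    (iterated quadratic approximations with cyclic updates).
    """
    data = _CoxData(x, time, event)
    b0 = np.zeros(data.p) if beta0 is None else np.asarray(beta0, dtype=float)
    return _cd_solve(data, lam, b0, max_outer=500, tol=tol)


def lasso_cox_path(
    x: np.ndarray,
    time,
    event,
    lambdas: np.ndarray,
    tol: float = 1e-6,
) -> np.ndarray:
    """Warm-started coefficient path over a decreasing penalty sequence."""
    data = _CoxData(x, time, event)
    betas = np.zeros((len(lambdas), data.p))
    b = np.zeros(data.p)
    for i, lam in enumerate(lambdas):
        b = _cd_solve(data, lam, b, tol=tol)
        betas[i] = b
    return betas


@dataclass
class AgingSignatureModel:
    """Fitted LASSO-Cox aging signature (results object).

    ``coefficients`` are on the original pathway-score scale (standardization
    is internal); ``selected`` are the pathways with nonzero coefficients at
    the chosen penalty.
    """

    candidates: list[str]
    selected: list[str]
    coefficients: pd.Series
    lambda_path: np.ndarray
    cv_mean: np.ndarray
    cv_se: np.ndarray
    chosen_lambda: float
    lambda_min: float
    n_folds: int
    fold_seed: int
    n_train: int
    n_events: int

    def predict(self, x: pd.DataFrame) -> pd.Series:
        """Aging signature = linear predictor over the selected pathways."""
        return aging_signature(self, x)

    def cv_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lambda": self.lambda_path,
                "cv_deviance": self.cv_mean,
                "cv_se": self.cv_se,
            }
        )

    def summary(self) -> str:
        lines = [
            "Network-based aging signature (LASSO-Cox, Breslow ties)",
            f"  training samples: {self.n_train}  events: {self.n_events}",
            f"  candidate pathways: {len(self.candidates)}",
            f"  folds: {self.n_folds}  fold seed: {self.fold_seed}",
            f"  lambda (min rule): {self.lambda_min:.5g}",
            f"  lambda (chosen):   {self.chosen_lambda:.5g}",
            f"  selected pathways: {len(self.selected)}",
        ]
        for nm in self.selected:
            lines.append(f"    {nm:<30s} coef = {self.coefficients[nm]:+.4f}")
        return "\n".join(lines)

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coefficients.loc[self.selected]}
        ).rename_axis("pathway")


def fit_lasso_cox(
    x: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    n_folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 50,
    lambda_min_ratio: float = 1e-3,
    rule: str = "1se",
) -> AgingSignatureModel:
    """LASSO-Cox over pathway scores with cross-validated penalty choice.

    ``x`` is pathways x samples (or samples x pathways with named columns).
    Predictors are standardized internally and coefficients returned on the
    original scale. The penalty path is log-spaced from ``lambda_max`` down;
    K-fold cross-validation scores each penalty by the Verweij-van
    Houwelingen partial-likelihood deviance, and the chosen penalty is the
    largest whose CV deviance is within one standard error of the minimum
    (``rule='min'`` takes the minimizer instead). The final model is refit
    on all supplied samples at the chosen penalty.
    """
    if isinstance(x, pd.DataFrame):
        # accept pathways x samples orientation (rows = pathways)
        if x.shape[0] < x.shape[1] and len(time) == x.shape[1]:
            x = x.T
        names = list(x.columns)
        xm = x.to_numpy(dtype=float)
    else:
        xm = np.asarray(x, dtype=float)
        names = [f"p{j}" for j in range(xm.shape[1])]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    n, p = xm.shape
    if event.sum() < n_folds:
        raise ValueError("need at least one event per fold")

    center = xm.mean(axis=0)
    scale = xm.std(axis=0)
    if (scale == 0).any():
        raise ValueError("constant pathway score column")
    xs = (xm - center) / scale

    lam_max = lasso_lambda_max(xs, time, event)
    lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)

    rng = np.random.default_rng(seed)
    # event-stratified folds so every training fold keeps events
    folds = np.empty(n, dtype=int)
    for cls in (0, 1):
        idx = np.nonzero(event == cls)[0]
        idx = rng.permutation(idx)
        folds[idx] = np.arange(idx.size) % n_folds
    full = _CoxData(xs, time, event)
    dev = np.zeros((n_folds, len(lambdas)))
    for k in range(n_folds):
        train = folds != k
        if event[train].sum() < 1:
            raise ValueError(f"fold {k} leaves no events for training")
        betas = lasso_cox_path(xs[train], time[train], event[train], lambdas)
        tr = _CoxData(xs[train], time[train], event[train])
        for i, b in enumerate(betas):
            dev[k, i] = -2.0 * (full.loglik(b) - tr.loglik(b))
    cv_mean = dev.mean(axis=0)
    cv_se = dev.std(axis=0, ddof=1) / np.sqrt(n_folds)
    i_min = int(np.argmin(cv_mean))
    if rule == "1se":
        bound = cv_mean[i_min] + cv_se[i_min]
        i_chosen = int(np.nonzero(cv_mean <= bound)[0][0])  # largest lambda
    else:
        i_chosen = i_min

    beta_std = lasso_cox_path(xs, time, event, lambdas[: i_chosen + 1])[-1]
    coef = pd.Series(beta_std / scale, index=names)
    selected = [nm for nm, c in coef.items() if c != 0.0]
    return AgingSignatureModel(
        candidates=names,
        selected=selected,
        coefficients=coef,
        lambda_path=lambdas,
        cv_mean=cv_mean,
        cv_se=cv_se,
        chosen_lambda=float(lambdas[i_chosen]),
        lambda_min=float(lambdas[i_min]),
        n_folds=n_folds,
        fold_seed=seed,
        n_train=n,
        n_events=int(event.sum()),
    )


class PenalizedCoxSignature:
    """Model object for the network-based aging signature.

    ``PenalizedCoxSignature(pathway_scores, time, event).fit(seed=...)``
    returns an :class:`AgingSignatureModel` results object; see
    :func:`fit_lasso_cox` for the procedure.
    """

    def __init__(self, pathway_scores: pd.DataFrame, time, event):
        self.pathway_scores = pathway_scores
        self.time = np.asarray(time, dtype=float)
        self.event = np.asarray(event, dtype=float)

    def fit(self, n_folds: int = 10, seed: int = 0, **kwargs) -> AgingSignatureModel:
        return fit_lasso_cox(
            self.pathway_scores, self.time, self.event,
            n_folds=n_folds, seed=seed, **kwargs,
        )


def aging_signature(model: AgingSignatureModel, x: pd.DataFrame) -> pd.Series:
    """Per-sample signature: sum of coefficient x pathway score over selected pathways.

    ``x`` is pathways x samples; a missing selected pathway row is an error,
    extra rows are ignored.
    """
    missing = [pw for pw in model.selected if pw not in x.index]
    if missing:
        raise KeyError(f"pathway scores missing selected pathways: {missing}")
    if not model.selected:
        return pd.Series(0.0, index=x.columns)
    sub = x.loc[model.selected].to_numpy(dtype=float)
    coefs = model.coefficients.loc[model.selected].to_numpy()
    return pd.Series(coefs @ sub, index=x.columns)


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank evaluation


@dataclass
class SurvivalCurve:
    """Product-limit survival estimate for one group."""

    label: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray


def median_split(values: pd.Series | np.ndarray) -> np.ndarray:
    """High/low labels by median; values tied with the median go low."""
    v = np.asarray(values, dtype=float)
    return v > np.median(v)


def km_logrank(
    time: np.ndarray,
    event: np.ndarray,
    group: np.ndarray,
    labels: tuple[str, str] = ("low", "high"),
) -> tuple[dict[str, SurvivalCurve], float, float]:
    """Kaplan-Meier curves per group and the two-group log-rank test.

    ``group`` is boolean (True = second label). Returns
    ``(curves, chi_square, p)``; with zero events overall both curves are
    flat at 1 and p = 1.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group, dtype=bool)
    if group.sum() == 0 or (~group).sum() == 0:
        raise ValueError("both groups must be non-empty")
    curves: dict[str, SurvivalCurve] = {}
    for flag, label in zip((False, True), labels):
        sel = group == flag
        kmf = KaplanMeierFitter()
        kmf.fit(time[sel], event[sel], label=label)
        grid = kmf.survival_function_.index.to_numpy(dtype=float)
        surv = kmf.survival_function_[label].to_numpy(dtype=float)
        at_risk = np.array(
            [int((time[sel] >= t).sum()) for t in grid], dtype=int
        )
        curves[label] = SurvivalCurve(
            label=label, times=grid, survival=surv, at_risk=at_risk
        )
    if event.sum() == 0:
        return curves, 0.0, 1.0
    res = logrank_test(time[~group], time[group], event[~group], event[group])
    return curves, float(res.test_statistic), float(res.p_value)


def split_train_test(
    samples: list[str], train_fraction: float = 0.5, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Random train/test split of sample ids (default 50/50), seeded."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(samples))
    n_train = int(round(train_fraction * len(samples)))
    train = [samples[i] for i in sorted(perm[:n_train])]
    test = [samples[i] for i in sorted(perm[n_train:])]
    return train, test
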