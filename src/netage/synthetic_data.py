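"""Synthetic cohorts with planted regulatory aging effects.

The generator emulates the statistical structure the pipeline is designed
to detect, without any external data:

* a random binary motif prior and a random symmetric PPI prior;
* expression from a TF-activity model — each gene is a noisy linear
  readout of its prior-regulator activities, and the *coupling strength*
  of that readout is what carries the planted biology: it increases with
  age for ``planted_up_genes`` (faster in smokers by
  ``smoking_acceleration``), decreases with age for ``planted_down_genes``,
  and fluctuates with a per-pathway latent regulatory program shared by
  the genes of each pathway;
* chrY gene expression is missing (NaN) in female samples;
* survival from a proportional-hazards model with exponential baseline on
  the pathway latents (the "true pathway activity"), censored by an
  independent exponential tuned to the requested censoring fraction.

Stronger coupling means stronger TF-gene coexpression, which is exactly
the evidence channel the network inference reads, so planted genes gain
indegree with age in the reconstructed single-sample networks.

Randomness: one root seed; per-component generators are spawned from a
``numpy.random.SeedSequence`` in a fixed documented order (prior, ppi,
covariates, activities, pathway latents, noise, survival, drugs), so the
same seed reproduces a bit-identical cohort and adding samples to one
component never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .drug_matching import DrugSignature
from .priors import MotifPrior, PPIPrior, build_ppi_prior

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "calibration_cohort_spec",
    "generate_cohort",
    "generate_drug_library",
    "generate_pathway_survival_cohort",
    "write_cohort",
]

_STREAMS = [
    "prior",
    "ppi",
    "covariates",
    "activities",
    "pathway_latents",
    "noise",
    "survival",
    "drugs",
]


@dataclass
class CohortSpec:
    """Generation parameters for one synthetic cohort.

    Defaults mirror the discovery-cohort conditions the pipeline targets:
    ages 21-70 years, about two-thirds ever-smokers and one-third female,
    and a small panel of Y-chromosome genes. ``age_slope`` is in coupling
    units per year of age; couplings are O(1), so the default 0.05 sweeps a
    planted gene's co-regulation strength across the sensitive range of the
    pairwise correlation (roughly 0.4-0.9) over the age span — detectable
    but not saturating at the default noise level (see the methods note
    for the calibration of this choice).
    """

    n_tfs: int = 20
    n_genes: int = 200
    n_samples: int = 120
    n_chry_genes: int = 6
    age_range: tuple[float, float] = (21.0, 70.0)
    frac_smokers: float = 0.66
    frac_female: float = 0.32
    planted_up_genes: list[str] | None = None
    planted_down_genes: list[str] | None = None
    age_slope: float = 0.05
    smoking_acceleration: float = 1.0
    noise_sd: float = 1.0
    survival_beta: dict[str, float] = field(default_factory=dict)
    censor_rate: float = 0.3
    seed: int = 0
    # generative details (kept fixed across the study conditions)
    n_pathways: int = 10
    base_coupling: float = 0.2
    pathway_coupling: float = 0.15
    module_size: int = 4
    mean_regulators: float = 5.0
    #: leading TF modules never reused by overflow pathways, so planted
    #: pathways (by convention the leading ones) keep exclusive regulators
    reserved_modules: int = 2
    #: mean number of decoy motif edges per gene: motif hits present in the
    #: prior that do not drive expression, as most real promoter motif
    #: occurrences are non-functional. Decoys densify the prior so the
    #: network response to co-regulation spreads over many TFs.
    decoy_regulators: float = 0.0
    baseline_hazard: float = np.log(2) / 1000.0  # median ~1000 days at eta=0

    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    def tf_ids(self) -> list[str]:
        return [f"TF{i:03d}" for i in range(self.n_tfs)]

    def pathway_names(self) -> list[str]:
        return [f"PATH{i:02d}" for i in range(self.n_pathways)]

    def validate(self) -> None:
        for name in ("n_tfs", "n_genes", "n_samples"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.n_chry_genes < self.n_genes:
            raise ValueError("n_chry_genes must be in [0, n_genes)")
        for name in ("frac_smokers", "frac_female", "censor_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.age_range[0] >= self.age_range[1] or self.age_range[0] <= 0:
            raise ValueError("age_range must be increasing and positive")
        if self.age_slope < 0:
            raise ValueError("age_slope must be >= 0")
        if self.smoking_acceleration < 1:
            raise ValueError("smoking_acceleration must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        up = set(self.planted_up_genes or [])
        down = set(self.planted_down_genes or [])
        if up & down:
            raise ValueError("planted_up_genes and planted_down_genes overlap")
        genes = set(self.gene_ids())
        if (up | down) - genes:
            raise ValueError("planted gene ids outside the gene universe")


@dataclass
class SyntheticCohort:
    """All inputs the pipeline consumes, plus the ground-truth record."""

    expression: pd.DataFrame
    motif_prior: MotifPrior
    ppi_prior: PPIPrior
    covariates: pd.DataFrame
    annotations: pd.DataFrame
    motif_hits: pd.DataFrame
    gene_sets: dict[str, list[str]]
    drug_library: list[DrugSignature]
    truth: dict


def _spawn(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {
        name: np.random.default_rng(child)
        for name, child in zip(_STREAMS, children)
    }


def _make_annotations(spec: CohortSpec) -> pd.DataFrame:
    """Gene annotation table; the last ``n_chry_genes`` genes sit on chrY."""
    genes = spec.gene_ids()
    autosomes = [f"chr{i}" for i in range(1, 23)] + ["chrX"]
    rows = []
    for i, g in enumerate(genes):
        on_y = i >= spec.n_genes - spec.n_chry_genes
        chrom = "chrY" if on_y else autosomes[i % len(autosomes)]
        rows.append(
            {
                "gene_id": g,
                "chromosome": chrom,
                "strand": "+" if i % 2 == 0 else "-",
                "tss": 10_000 + 5_000 * i,  # unique, promoters never overlap
            }
        )
    return pd.DataFrame(rows)


def _module_tfs(spec: CohortSpec, pathway_idx: int) -> list[int]:
    """The TFs forming a pathway's regulatory module.

    Modules are consecutive disjoint TF blocks. When there are more
    pathways than disjoint modules, the first pathways keep dedicated
    modules and the remainder share the rest round-robin: planted effects
    live in the leading pathways, so their regulatory programs never alias
    a null pathway's.
    """
    n = spec.n_tfs
    m = min(spec.module_size, n)
    n_modules = max(n // m, 1)
    if pathway_idx < n_modules:
        mod = pathway_idx
    else:
        skip = min(spec.reserved_modules, n_modules - 1)
        mod = skip + (pathway_idx - n_modules) % max(n_modules - skip, 1)
    return [(m * mod + k) % n for k in range(m)]


def _make_motif_prior(
    spec: CohortSpec,
    annotations: pd.DataFrame,
    pathway_index_of: dict[str, int],
    rng: np.random.Generator,
) -> tuple[MotifPrior, pd.DataFrame]:
    """Pathway-structured bipartite prior plus a hit table that reproduces it.

    Pathways are regulatory programs: each is anchored on a TF module, and
    a member gene is *functionally* regulated by its module TFs plus
    Poisson(mean_regulators - module_size) random others; genes outside
    any pathway (chrY panel) get 1 + Poisson(mean_regulators - 1) random
    functional regulators. Shared module TFs are what make pathway genes
    co-expressed, the evidence channel the network inference reads.

    On top of the functional edges, every gene receives
    Poisson(decoy_regulators) *decoy* motif edges — present in the prior
    (a motif occurrence in the promoter) but not wired into expression,
    as most real promoter motif matches are non-functional. For each prior
    edge one significant hit interval is placed at the gene's TSS (inside
    the promoter window on either strand), so rebuilding the prior from
    the hit table with the default window recovers it exactly.

    Returns ``(prior, hits, functional)`` where ``functional`` is the
    TF x gene 0/1 matrix of expression-driving edges (a subset of the
    prior's edges).
    """
    tfs, genes = spec.tf_ids(), spec.gene_ids()
    edges = np.zeros((spec.n_tfs, spec.n_genes))
    functional = np.zeros((spec.n_tfs, spec.n_genes))
    annot = annotations.set_index("gene_id")
    hit_rows = []
    for j, g in enumerate(genes):
        if g in pathway_index_of:
            module = _module_tfs(spec, pathway_index_of[g])
            extra = rng.poisson(max(spec.mean_regulators - len(module), 0))
            others = [t for t in range(spec.n_tfs) if t not in module]
            regs = list(module)
            if extra > 0 and others:
                regs += list(
                    rng.choice(others, size=min(extra, len(others)), replace=False)
                )
        else:
            k = min(1 + rng.poisson(spec.mean_regulators - 1), spec.n_tfs)
            regs = list(rng.choice(spec.n_tfs, size=k, replace=False))
        functional[regs, j] = 1.0
        n_decoys = rng.poisson(spec.decoy_regulators)
        free = [t for t in range(spec.n_tfs) if t not in set(regs)]
        if n_decoys > 0 and free:
            decoys = rng.choice(free, size=min(n_decoys, len(free)), replace=False)
            regs = regs + list(decoys)
        edges[regs, j] = 1.0
        tss = int(annot.loc[g, "tss"])
        for t in sorted(regs):
            hit_rows.append(
                {
                    "tf_id": tfs[t],
                    "chromosome": annot.loc[g, "chromosome"],
                    "start": tss,
                    "end": tss + 10,
                    "p_value": 1e-6,
                }
            )
    prior = MotifPrior(tfs=tfs, genes=genes, edges=edges)
    return prior, pd.DataFrame(hit_rows), functional


def _make_ppi(spec: CohortSpec, rng: np.random.Generator) -> PPIPrior:
    pairs = []
    tfs = spec.tf_ids()
    for i in range(spec.n_tfs):
        for j in range(i + 1, spec.n_tfs):
            if rng.random() < 0.2:
                pairs.append((tfs[i], tfs[j], float(rng.integers(150, 1000))))
    return build_ppi_prior(pairs, tfs)


def _make_covariates(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n_samples
    samples = [f"S{i:04d}" for i in range(n)]
    lo, hi = spec.age_range
    age = np.round(rng.uniform(lo, hi, n), 1)
    sex = np.where(rng.random(n) < spec.frac_female, "female", "male")
    smoking = np.where(rng.random(n) < spec.frac_smokers, "ever", "never")
    race = rng.choice(["white", "black", "other"], size=n, p=[0.8, 0.12, 0.08])
    stage = rng.choice(["I", "II", "III", "IV"], size=n, p=[0.5, 0.25, 0.17, 0.08])
    batch = rng.choice(["B0", "B1"], size=n)
    rin = np.round(rng.normal(7.5, 0.6, n), 2)
    ischemic = np.round(rng.exponential(8.0, n), 2)
    return pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "smoking": smoking,
            "race": race,
            "disease": "healthy",
            "stage": stage,
            "batch": batch,
            "rin": rin,
            "ischemic_time": ischemic,
        },
        index=pd.Index(samples, name="sample"),
    )


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a complete synthetic cohort from a validated spec.

    See the module docstring for the generative model. Identical specs
    (including seed) produce bit-identical cohorts.
    """
    spec.validate()
    rngs = _spawn(spec.seed)
    genes = spec.gene_ids()
    tfs = spec.tf_ids()

    annotations = _make_annotations(spec)

    # pathways partition the autosomal genes into consecutive blocks
    non_y = genes[: spec.n_genes - spec.n_chry_genes] if spec.n_chry_genes else genes
    blocks = np.array_split(np.arange(len(non_y)), spec.n_pathways)
    gene_sets = {
        name: [non_y[i] for i in block]
        for name, block in zip(spec.pathway_names(), blocks)
    }
    pathway_of: dict[str, str] = {}
    pathway_index_of: dict[str, int] = {}
    for pi, (name, members) in enumerate(gene_sets.items()):
        for g in members:
            pathway_of[g] = name
            pathway_index_of[g] = pi

    prior, hits, functional = _make_motif_prior(
        spec, annotations, pathway_index_of, rngs["prior"]
    )
    ppi = _make_ppi(spec, rngs["ppi"])
    cov = _make_covariates(spec, rngs["covariates"])

    up = list(spec.planted_up_genes) if spec.planted_up_genes is not None else list(
        gene_sets[spec.pathway_names()[0]]
    )
    down = (
        list(spec.planted_down_genes)
        if spec.planted_down_genes is not None
        else list(gene_sets[spec.pathway_names()[1]])
    )
    if set(up) & set(down):
        raise ValueError("planted up/down gene sets overlap")

    n = spec.n_samples
    age = cov["age"].to_numpy()
    smoker = (cov["smoking"] == "ever").to_numpy()
    accel = np.where(smoker, spec.smoking_acceleration, 1.0)

    activities = rngs["activities"].standard_normal((spec.n_tfs, n))
    latents = rngs["pathway_latents"].standard_normal((spec.n_pathways, n))
    pw_index = {name: i for i, name in enumerate(spec.pathway_names())}

    lo, hi = spec.age_range
    up_set, down_set = set(up), set(down)
    coupling = np.full((spec.n_genes, n), spec.base_coupling)
    for j, g in enumerate(genes):
        if g in pathway_of:
            coupling[j] += spec.pathway_coupling * latents[pw_index[pathway_of[g]]]
        if g in up_set:
            coupling[j] += spec.age_slope * (age - lo) * accel
        elif g in down_set:
            coupling[j] += spec.age_slope * (hi - age) * accel

    # gene-specific positive regulator loadings (unit L2 norm per gene)
    # over the FUNCTIONAL edges only — decoy motif edges stay silent:
    # pathway partners stay positively co-expressed while the chi-square
    # noise of per-sample co-variation averages over the module factors.
    loadings = functional * rngs["prior"].uniform(
        0.5, 1.5, size=functional.shape
    )
    norms = np.sqrt(np.maximum((loadings**2).sum(axis=0), 1e-12))
    signal = (loadings.T @ activities) / norms[:, None]
    baseline = rngs["noise"].uniform(5.0, 15.0, spec.n_genes)
    noise = rngs["noise"].standard_normal((spec.n_genes, n)) * spec.noise_sd
    values = baseline[:, None] + coupling * signal + noise
    values = np.maximum(values, 0.0)
    expr = pd.DataFrame(values, index=genes, columns=cov.index)

    y_genes = genes[spec.n_genes - spec.n_chry_genes :] if spec.n_chry_genes else []
    females = cov.index[cov["sex"] == "female"]
    if y_genes and len(females):
        expr.loc[y_genes, females] = np.nan

    # survival: exponential PH on true pathway activity, exponential censoring
    beta = np.zeros(spec.n_pathways)
    for name, b in spec.survival_beta.items():
        beta[pw_index[name]] = b
    eta = beta @ latents
    hazard = spec.baseline_hazard * np.exp(eta)
    rng_s = rngs["survival"]
    t_event = rng_s.exponential(1.0 / hazard)
    if spec.censor_rate > 0:
        censor_hazard = hazard * spec.censor_rate / (1.0 - spec.censor_rate)
        t_censor = rng_s.exponential(1.0 / censor_hazard)
    else:
        t_censor = np.full(n, np.inf)
    cov["survival_time"] = np.round(np.minimum(t_event, t_censor), 2)
    cov["event"] = (t_event <= t_censor).astype(int)

    library = generate_drug_library(
        n_drugs=50,
        universe=list(non_y),
        reversal_drug_ids=["DRUG_REVERSER"],
        up=up,
        down=down,
        seed=int(rngs["drugs"].integers(2**31 - 1)),
    )

    truth = {
        "planted_up_genes": up,
        "planted_down_genes": down,
        "age_slope": spec.age_slope,
        "smoking_acceleration": spec.smoking_acceleration,
        "pathway_of_gene": pathway_of,
        "survival_beta": dict(spec.survival_beta),
        "active_pathways": [k for k, v in spec.survival_beta.items() if v != 0],
        "reversal_drugs": ["DRUG_REVERSER"],
        "chry_genes": list(y_genes),
        "seed": spec.seed,
    }
    return SyntheticCohort(
        expression=expr,
        motif_prior=prior,
        ppi_prior=ppi,
        covariates=cov,
        annotations=annotations,
        motif_hits=hits,
        gene_sets=gene_sets,
        drug_library=library,
        truth=truth,
    )


def calibration_cohort_spec(seed: int, age_slope: float = 0.05) -> CohortSpec:
    """Study conditions for the differential-targeting calibration.

    A 2,000-gene, 100-TF, 120-sample cohort: 50 pathways, each on its own
    dedicated 2-TF module, the leading pathway aging up and the second
    aging down (78 planted genes, ~4% of the universe). A realistic TF
    count matters here: the indegree sums edge weights over all TFs, and
    with too few TFs the z-score-conditioned weights nearly cancel, making
    the single-sample response to co-regulation unstable; at 100 TFs the
    response is coherent. Planted couplings sweep the pairwise
    correlation's sensitive range in opposite directions across the age
    span.
    """
    spec = CohortSpec(
        n_genes=2000,
        n_tfs=100,
        n_samples=120,
        module_size=2,
        n_pathways=50,
        mean_regulators=2,
        age_slope=age_slope,
        seed=seed,
    )
    genes = spec.gene_ids()
    non_y = genes[: spec.n_genes - spec.n_chry_genes]
    blocks = np.array_split(np.arange(len(non_y)), spec.n_pathways)
    spec.planted_up_genes = [non_y[i] for i in blocks[0]]
    spec.planted_down_genes = [non_y[i] for i in blocks[1]]
    return spec


def generate_drug_library(
    n_drugs: int,
    universe: list[str],
    reversal_drug_ids: list[str],
    up: list[str],
    down: list[str],
    seed: int = 0,
    sig_size: tuple[int, int] | None = None,
) -> list[DrugSignature]:
    """Synthetic drug-signature library with optional planted reversers.

    A planted reverser's up-set contains the query's ``down`` genes and its
    down-set the query's ``up`` genes (a perfect reversal of the query);
    the other drugs draw disjoint up/down sets uniformly from the universe,
    with sizes uniform in ``sig_size`` (default: matched to the query
    sizes). Drug ids are ``D000..``; planted reversers keep their given ids.
    """
    if len(universe) == 0:
        raise ValueError("empty gene universe")
    stray = (set(up) | set(down)) - set(universe)
    if stray:
        raise ValueError(f"query genes outside universe, e.g. {next(iter(stray))!r}")
    rng = np.random.default_rng(seed)
    uni = list(universe)
    lo, hi = sig_size if sig_size is not None else (
        max(1, min(len(up), len(down))),
        max(len(up), len(down)),
    )
    library: list[DrugSignature] = []
    for rid in reversal_drug_ids:
        library.append(DrugSignature(drug_id=rid, up=set(down), down=set(up)))
    k = 0
    while len(library) < n_drugs:
        n_up = int(rng.integers(lo, hi + 1))
        n_down = int(rng.integers(lo, hi + 1))
        pick = rng.choice(len(uni), size=min(n_up + n_down, len(uni)), replace=False)
        library.append(
            DrugSignature(
                drug_id=f"D{k:03d}",
                up={uni[i] for i in pick[:n_up]},
                down={uni[i] for i in pick[n_up:]},
            )
        )
        k += 1
    return library


def generate_pathway_survival_cohort(
    n_samples: int = 400,
    n_pathways: int = 28,
    n_active: int = 4,
    beta: float = 0.8,
    censor_rate: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Pathway-score-stage cohort for survival-signature studies.

    Emulates the *output* of the pathway-scoring stage directly — a
    pathways x samples score matrix with standard-normal scores — at a
    sample size where full network inference would be gratuitous. The
    first ``n_active`` pathways drive the hazard with alternating-sign
    log-hazard coefficients ``+/-beta``; survival has an exponential
    baseline and independent exponential censoring tuned to
    ``censor_rate``. Chronological age is drawn independently of survival,
    so an age split carries no prognostic signal by construction.

    Returns ``(scores, covariates, truth)``.
    """
    if n_active > n_pathways:
        raise ValueError("n_active must be <= n_pathways")
    rng = np.random.default_rng(seed)
    pathways = [f"PATH{i:02d}" for i in range(n_pathways)]
    samples = [f"S{i:04d}" for i in range(n_samples)]
    x = rng.standard_normal((n_pathways, n_samples))
    betas = np.zeros(n_pathways)
    for i in range(n_active):
        betas[i] = beta * (1 if i % 2 == 0 else -1)
    eta = betas @ x
    base = np.log(2) / 1000.0
    hazard = base * np.exp(eta)
    t_event = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        t_censor = rng.exponential(
            (1.0 - censor_rate) / (hazard * censor_rate)
        )
    else:
        t_censor = np.full(n_samples, np.inf)
    cov = pd.DataFrame(
        {
            "age": np.round(rng.uniform(40, 80, n_samples), 1),
            "survival_time": np.minimum(t_event, t_censor),
            "event": (t_event <= t_censor).astype(int),
        },
        index=pd.Index(samples, name="sample"),
    )
    scores = pd.DataFrame(x, index=pathways, columns=samples)
    truth = {
        "active_pathways": pathways[:n_active],
        "beta": {p: float(b) for p, b in zip(pathways, betas) if b != 0},
        "censor_rate": censor_rate,
        "seed": seed,
    }
    return scores, cov, truth


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, str]:
    """Write every cohort component in the formats the pipeline reads."""
    from pathlib import Path

    from . import io

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "covariates": out / "covariates.tsv",
        "annotations": out / "annotations.tsv",
        "motif_hits": out / "motif_hits.bed",
        "ppi": out / "ppi_edges.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "drug_library": out / "drug_library.tsv",
        "truth": out / "truth.json",
    }
    io.write_expression(cohort.expression, paths["expression"])
    io.write_covariates(cohort.covariates, paths["covariates"])
    io.write_annotations(cohort.annotations, paths["annotations"])
    io.write_motif_hits(cohort.motif_hits, paths["motif_hits"])
    ppi = cohort.ppi_prior
    rows = []
    for i in range(len(ppi.tfs)):
        for j in range(i + 1, len(ppi.tfs)):
            if ppi.scores[i, j] > 0:
                rows.append((ppi.tfs[i], ppi.tfs[j], ppi.scores[i, j] * 1000))
    io.write_ppi_edges(pd.DataFrame(rows, columns=["tf_a", "tf_b", "score"]), paths["ppi"])
    io.write_gmt(cohort.gene_sets, paths["gene_sets"])
    io.write_drug_library(cohort.drug_library, paths["drug_library"])
    io.write_json(cohort.truth, paths["truth"])
    return {k: str(v) for k, v in paths.items()}
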