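"""End-to-end orchestration: simulate/load -> priors -> networks -> statistics.

``run_pipeline`` executes the stages in dependency order on a config
mapping (usually loaded from YAML), writes every intermediate artifact
under the output directory, and emits a JSON manifest with parameter
values, per-stage row/edge counts and a sha256 checksum of every file, so
a re-run with the same config and seed is byte-identical and every number
in the outputs is traceable to a stage.

Stage order: simulate, priors, networks, targeting, gsea, signature,
drugs. With a ``simulate`` block the cohort is generated; otherwise the
``inputs`` block must name the expression/covariate/prior files.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .enrichment import GeneSetCollection, preranked_gsea
from .network_inference import PandaConfig, run_lioness, run_lioness_by_sex
from .priors import (
    build_motif_prior,
    build_ppi_prior,
    make_sex_specific_prior,
    preprocess_expression,
)
from .survival_signature import (
    aging_signature,
    fit_lasso_cox,
    km_logrank,
    median_split,
    pathway_score_matrix,
    split_train_test,
)
from .synthetic_data import CohortSpec, generate_cohort, write_cohort
from .targeting import (
    DifferentialTargetingModel,
    concat_indegrees,
    select_age_genes,
)
from .drug_matching import match_drugs

log = logging.getLogger("netage")

__all__ = ["run_pipeline", "DEFAULT_CONFIG"]

#: the constants of the analysis; every stage parameter is config-exposed.
DEFAULT_CONFIG = {
    "priors": {
        "upstream": 750,          # promoter window [-750, +250] around the TSS
        "downstream": 250,
        "p_threshold": 1e-5,      # motif-hit significance cutoff
        "tpm_threshold": 1.0,     # drop genes < 1 TPM ...
        "sample_fraction": 0.10,  # ... in at least 10% of samples
    },
    "panda": {"alpha": 0.1, "tolerance": 1e-3, "max_iterations": 200},
    "targeting": {
        "terms": ["age", "sex", "smoking"],
        "coefficient": "age",
        "moderated": True,
        "p_threshold": 0.05,
    },
    "gsea": {"min_size": 15, "max_size": 500, "n_perm": 10_000},
    "signature": {
        "train_fraction": 0.5,
        "n_folds": 10,
        "candidate_fdr": 0.05,
    },
    "drugs": {"n_resamples": 10_000},
    "stratify_by_sex": False,
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, outdir: str | Path, seed: int = 0) -> dict:
    """Run all configured stages; returns (and writes) the run manifest."""
    cfg = _merge(DEFAULT_CONFIG, config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "config": cfg, "stages": {}}

    def record(stage: str, outputs: dict[str, Path], **info) -> None:
        manifest["stages"][stage] = {
            "outputs": {k: {"path": str(p), "sha256": _sha256(Path(p))} for k, p in outputs.items()},
            "info": info,
        }
        log.info("stage %s done: %s", stage, info)

    # --- simulate or load ---------------------------------------------------
    if "simulate" in cfg:
        sim = dict(cfg["simulate"])
        sim.setdefault("seed", seed)
        if "age_range" in sim:
            sim["age_range"] = tuple(sim["age_range"])
        spec = CohortSpec(**sim)
        cohort = generate_cohort(spec)
        paths = write_cohort(cohort, out / "cohort")
        record(
            "simulate",
            {k: Path(v) for k, v in paths.items()},
            n_genes=spec.n_genes,
            n_tfs=spec.n_tfs,
            n_samples=spec.n_samples,
        )
        expression = cohort.expression
        covariates = cohort.covariates
        annotations = cohort.annotations
        hits = cohort.motif_hits
        ppi_prior = cohort.ppi_prior
        gene_sets = cohort.gene_sets
        drug_library = cohort.drug_library
        tf_universe = cohort.motif_prior.tfs
    else:
        inputs = cfg["inputs"]
        expression = io.read_expression(inputs["expression"])
        covariates = io.read_covariates(inputs["covariates"])
        annotations = io.read_annotations(inputs["annotations"])
        hits = io.read_motif_hits(inputs["motif_hits"])
        ppi_edges = io.read_ppi_edges(inputs["ppi"])
        gene_sets = io.read_gmt(inputs["gene_sets"])
        drug_library = (
            io.read_drug_library(inputs["drug_library"])
            if "drug_library" in inputs
            else []
        )
        tf_universe = sorted(hits["tf_id"].unique())
        ppi_prior = build_ppi_prior(ppi_edges, tf_universe)

    # --- priors -------------------------------------------------------------
    pc = cfg["priors"]
    motif = build_motif_prior(
        hits,
        annotations,
        upstream=pc["upstream"],
        downstream=pc["downstream"],
        p_threshold=pc["p_threshold"],
        tfs=tf_universe,
    )
    expression = preprocess_expression(
        expression,
        covariates,
        tpm_threshold=pc["tpm_threshold"],
        sample_fraction=pc["sample_fraction"],
        prior_genes=motif.genes,
        annotations=annotations,
    )
    motif = _subset_prior(motif, list(expression.index))
    prior_paths = {}
    for sex in ("female", "male"):
        sp = make_sex_specific_prior(motif, sex, annotations)
        p = out / f"motif_prior_{sex}.tsv"
        io.write_prior_edges(sp, p)
        prior_paths[f"motif_{sex}"] = p
    record(
        "priors",
        prior_paths,
        n_edges=motif.n_edges,
        n_genes_kept=expression.shape[0],
    )

    # --- networks -----------------------------------------------------------
    panda_cfg = PandaConfig(**cfg["panda"])
    if cfg.get("stratify_by_sex"):
        priors_by_sex = {
            s: make_sex_specific_prior(motif, s, annotations)
            for s in ("female", "male")
        }
        nets = run_lioness_by_sex(
            expression, covariates, priors_by_sex, ppi_prior, panda_cfg
        )
        scores = concat_indegrees(nets)
    else:
        nets = run_lioness(expression, motif, ppi_prior, panda_cfg)
        scores = concat_indegrees({"all": nets})
    scores_path = out / "targeting_scores.tsv"
    scores.to_csv(scores_path, sep="\t", index_label="gene")
    record("networks", {"targeting_scores": scores_path}, n_samples=scores.shape[1])

    # --- differential targeting ----------------------------------------------
    tc = cfg["targeting"]
    model = DifferentialTargetingModel(
        scores,
        covariates,
        terms=tc["terms"],
        coefficient=tc["coefficient"],
    )
    result = model.fit(moderated=tc["moderated"])
    table = result.to_frame()
    table["fdr"] = np.nan
    ok = np.isfinite(result.best_p)
    from .enrichment import bh_adjust

    table.loc[ok, "fdr"] = bh_adjust(result.best_p[ok])
    targeting_path = out / "differential_targeting.tsv"
    table.to_csv(targeting_path, sep="\t")
    up, down = select_age_genes(result, tc["p_threshold"])
    record(
        "targeting",
        {"differential_targeting": targeting_path},
        n_up=len(up),
        n_down=len(down),
        n_samples_used=result.n_samples_used,
    )

    # --- enrichment -----------------------------------------------------------
    gc = cfg["gsea"]
    ranked = pd.Series(result.best_t, index=result.genes).dropna()
    enr = preranked_gsea(
        ranked,
        GeneSetCollection(gene_sets),
        min_size=gc["min_size"],
        max_size=gc["max_size"],
        n_perm=gc["n_perm"],
        seed=seed + 1,
    )
    gsea_path = out / "gsea.tsv"
    enr.table.to_csv(gsea_path, sep="\t")
    record(
        "gsea",
        {"gsea": gsea_path},
        n_sets_tested=len(enr.table),
        n_excluded=len(enr.excluded),
    )

    # --- aging signature -------------------------------------------------------
    sc = cfg["signature"]
    sig_info: dict = {}
    sig_outputs: dict[str, Path] = {}
    if "survival_time" in covariates.columns and covariates["event"].sum() >= sc["n_folds"]:
        candidates = list(enr.significant(sc["candidate_fdr"]).index)
        if len(candidates) < 2:
            candidates = list(enr.table.index)
        pw_scores = pathway_score_matrix(
            scores, {k: gene_sets[k] for k in candidates}
        )
        train, test = split_train_test(
            list(pw_scores.columns), sc["train_fraction"], seed + 2
        )
        sig_model = fit_lasso_cox(
            pw_scores[train],
            covariates.loc[train, "survival_time"].to_numpy(),
            covariates.loc[train, "event"].to_numpy(),
            n_folds=sc["n_folds"],
            seed=seed + 3,
        )
        model_path = out / "aging_signature.json"
        io.write_json(
            {
                "candidates": sig_model.candidates,
                "selected": sig_model.selected,
                "coefficients": sig_model.coefficients.to_dict(),
                "chosen_lambda": sig_model.chosen_lambda,
                "lambda_path": sig_model.lambda_path,
                "cv_mean": sig_model.cv_mean,
                "cv_se": sig_model.cv_se,
            },
            model_path,
        )
        sig_outputs["model"] = model_path
        sig_info["n_selected"] = len(sig_model.selected)
        if sig_model.selected and test:
            signature = aging_signature(sig_model, pw_scores[test])
            sig_path = out / "signature_test.tsv"
            signature.rename("signature").to_csv(sig_path, sep="\t")
            sig_outputs["signature_test"] = sig_path
            grp = median_split(signature)
            _, chi2, p = km_logrank(
                covariates.loc[test, "survival_time"].to_numpy(),
                covariates.loc[test, "event"].to_numpy(),
                grp,
            )
            sig_info["logrank_chi2"] = chi2
            sig_info["logrank_p"] = p
    else:
        sig_info["skipped"] = "no usable survival data"
    record("signature", sig_outputs, **sig_info)

    # --- drug matching ---------------------------------------------------------
    dc = cfg["drugs"]
    drug_info: dict = {}
    drug_outputs: dict[str, Path] = {}
    if drug_library and up and down:
        universe = [g for g in expression.index]
        results = match_drugs(
            up,
            down,
            drug_library,
            universe,
            n_resamples=dc["n_resamples"],
            seed=seed + 4,
        )
        drug_path = out / "drug_matches.tsv"
        pd.DataFrame(
            [
                {"drug": r.drug_id, "score": r.score, "p": r.p, **r.overlap}
                for r in results
            ]
        ).to_csv(drug_path, sep="\t", index=False)
        drug_outputs["drug_matches"] = drug_path
        drug_info["top_drug"] = results[0].drug_id
        drug_info["n_significant"] = sum(r.p < 0.05 for r in results)
    else:
        drug_info["skipped"] = "empty gene lists or drug library"
    record("drugs", drug_outputs, **drug_info)

    manifest_path = out / "manifest.json"
    io.write_json(manifest, manifest_path)
    return manifest


def _subset_prior(motif, genes: list[str]):
    from .priors import MotifPrior

    gi = {g: j for j, g in enumerate(motif.genes)}
    cols = [gi[g] for g in genes]
    return MotifPrior(tfs=motif.tfs, genes=genes, edges=motif.edges[:, cols])
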