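"""End-to-end orchestration on synthetic cohorts.

``run_pipeline`` executes the full analysis plan on generated data:
simulate a training cohort, apply platform artifacts, SNP QC, ancestry
MDS, the per-SNP association scan with genomic control, GREML
heritability with relatedness pruning and the liability transform,
cross-validated sparse risk models over an E[FP] grid with covariate-
adjusted AUCs, external validation on an independently simulated cohort,
the family sporadic-case simulation, and a liability-conversion summary
table.  All outputs are TSV/JSON under the run directory, with a
provenance manifest (config, stage seeds, stage counts).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .assoc import QCConfig, attach_pcs, genomic_control_lambda, logistic_lrt_scan, qc_filter
from .aucs import covariate_adjusted_auc, default_strata
from .cohort import ArchitectureSpec, Cohort, inject_platform_artifacts, simulate_cohort, write_cohort
from .config import RunConfig
from .families import FIRST_DEGREE_SET, FULL_RELATIVE_SET, build_default_pedigree, simulate_families, sporadic_proportion
from .greml import compute_grm, prune_related, reml_h2
from .liability import h2_from_relative_risk, max_auc_from_h2, prop_additive_explained, v_from_auc
from .sparse import fit_model_series, matched_cv_folds, predict_scores

log = logging.getLogger("archpipe")

__all__ = ["run_pipeline", "make_fixtures", "liability_conversion_table"]


def _stage(name: str):
    log.info("stage %s", name)
    return time.time()


def liability_conversion_table(
    K: float,
    lambdas: tuple[float, ...] = (3.0, 3.92, 7.76, 2.95),
    h2s: tuple[float, ...] = (0.272, 0.35, 0.456, 0.60, 1.0),
    auc_ref: float = 0.6,
) -> pd.DataFrame:
    """Conversion summary: lambda -> h2 and h2 -> (AUCmax, v at ``auc_ref``)."""
    rows = []
    for lam in lambdas:
        h2 = h2_from_relative_risk(lam, "first", K)
        rows.append(
            {
                "input": f"lambda_first={lam}",
                "h2_liability": h2,
                "auc_max": max_auc_from_h2(min(h2, 1.0), K),
                "v_at_ref_auc": v_from_auc(auc_ref, K),
                "prop_additive_at_ref_auc": prop_additive_explained(auc_ref, min(h2, 1.0), K),
            }
        )
    for h2 in h2s:
        rows.append(
            {
                "input": f"h2={h2}",
                "h2_liability": h2,
                "auc_max": max_auc_from_h2(h2, K),
                "v_at_ref_auc": v_from_auc(auc_ref, K),
                "prop_additive_at_ref_auc": prop_additive_explained(auc_ref, h2, K),
            }
        )
    return pd.DataFrame(rows)


def _simulate_from_config(cfg: RunConfig, n_case: int, n_control: int, seed: int) -> Cohort:
    c = cfg["cohort"]
    spec = ArchitectureSpec(
        m=c["m"],
        m_causal=c["m_causal"],
        h2_l=c["h2_l"],
        K=c["K"],
        maf_dist=("uniform", c["maf_low"], c["maf_high"]),
        seed=seed,
    )
    return simulate_cohort(spec, n_case, n_control)


def run_pipeline(cfg: RunConfig, out_dir: str | Path | None = None) -> Path:
    """Run every stage; returns the run directory."""
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(message)s")
    out = Path(out_dir if out_dir is not None else cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": cfg.data,
        "stage_seeds": {},
        "counts": {},
        "timings_s": {},
    }
    cfg_text = yaml.safe_dump(cfg.data, sort_keys=True)
    manifest["config_sha256"] = hashlib.sha256(cfg_text.encode()).hexdigest()

    # --- cohort ------------------------------------------------------------
    t0 = _stage("simulate")
    seed_cohort = cfg.stage_seed("cohort")
    manifest["stage_seeds"]["cohort"] = seed_cohort
    cc = cfg["cohort"]
    cohort = _simulate_from_config(cfg, cc["n_case"], cc["n_control"], seed_cohort)
    pl = cfg["platform"]
    cohort = inject_platform_artifacts(
        cohort,
        pl["frac_platform2"],
        (pl["missing_v1"], pl["missing_v2"]),
        pl["error_rate"],
        seed=cfg.stage_seed("platform"),
    )
    write_cohort(cohort, out / "cohort")
    manifest["counts"]["cohort"] = {"n": cohort.n_samples, "m": cohort.n_snps}
    manifest["timings_s"]["simulate"] = round(time.time() - t0, 2)

    # --- qc + mds + association -------------------------------------------
    t0 = _stage("qc+assoc")
    qc = QCConfig(
        min_call_rate=cfg["qc"]["min_call_rate"],
        min_maf=cfg["qc"]["min_maf"],
        hwe_alpha=cfg["qc"]["hwe_alpha"],
    )
    cohort_qc, qc_report = qc_filter(cohort, qc)
    qc_report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    cohort_qc = attach_pcs(cohort_qc, cfg["mds"]["k"])
    covars = tuple(cfg["assoc"]["covariates"])
    scan = logistic_lrt_scan(cohort_qc, covars, qc_report=qc_report)
    scan.to_csv(out / "assoc.tsv", sep="\t", index=False)
    lam_gc = genomic_control_lambda(scan["p_lrt"].to_numpy())
    manifest["counts"]["qc"] = {
        "snps_in": cohort.n_snps,
        "snps_pass": cohort_qc.n_snps,
    }
    manifest["counts"]["assoc"] = {"lambda_gc": lam_gc}
    manifest["timings_s"]["qc_assoc"] = round(time.time() - t0, 2)

    # --- greml -------------------------------------------------------------
    t0 = _stage("greml")
    gr = cfg["greml"]
    sub = cohort_qc
    if sub.n_samples > gr["max_n"]:
        keep = np.sort(
            np.random.default_rng(cfg.stage_seed("greml")).choice(
                sub.n_samples, gr["max_n"], replace=False
            )
        )
        sub = Cohort(sub.samples.iloc[keep].reset_index(drop=True), sub.genotypes[keep], sub.snps, sub.spec)
    grm = compute_grm(sub.genotypes, sub.samples["sample_id"])
    retained = prune_related(grm, gr["prune_threshold"])
    ridx = [grm.sample_ids.index(s) for s in retained]
    import dataclasses

    grm_p = dataclasses.replace(
        grm,
        values=grm.values[np.ix_(ridx, ridx)],
        sample_ids=tuple(retained),
    )
    mask = sub.samples["sample_id"].isin(retained).to_numpy()
    pcs = [f"pc{i + 1}" for i in range(gr["n_pcs"]) if f"pc{i + 1}" in sub.samples]
    Xc = sub.samples.loc[mask, ["sex"] + pcs].to_numpy(dtype=float)
    fit = reml_h2(grm_p, sub.status[mask], Xc, K=cc["K"])
    pd.DataFrame(
        [
            {
                "h2_obs": fit.h2_obs,
                "se_obs": fit.se_obs,
                "h2_liability": fit.h2_liab,
                "ci_low": fit.ci_liab[0],
                "ci_high": fit.ci_liab[1],
                "K": fit.K,
                "P": fit.P,
                "n": int(mask.sum()),
                "converged": fit.converged,
            }
        ]
    ).to_csv(out / "greml.tsv", sep="\t", index=False)
    manifest["counts"]["greml"] = {"n_used": int(mask.sum()), "pruned": int((~mask).sum())}
    manifest["timings_s"]["greml"] = round(time.time() - t0, 2)

    # --- risk prediction with internal CV ----------------------------------
    t0 = _stage("risk")
    rk = cfg["risk"]
    seed_risk = cfg.stage_seed("risk")
    folds = matched_cv_folds(cohort_qc, rk["n_folds"], seed=seed_risk)
    efp_grid = tuple(rk["efp_grid"])
    oof = {b: np.zeros(cohort_qc.n_samples) for b in efp_grid}
    sizes = {b: [] for b in efp_grid}
    for f in range(1, rk["n_folds"] + 1):
        train = folds.fold != f
        models = fit_model_series(cohort_qc, efp_grid, sample_mask=train)
        for b, mdl in zip(efp_grid, models):
            oof[b][~train] = predict_scores(mdl, cohort_qc)[~train]
            sizes[b].append(mdl.size)
    strata = default_strata(
        cohort_qc.samples.assign(fold=folds.fold), extra=("fold", "platform")
    )
    rows = []
    for b in efp_grid:
        res = covariate_adjusted_auc(oof[b], cohort_qc.status, strata)
        rows.append(
            {
                "efp_bound": b,
                "avg_snps": float(np.mean(sizes[b])),
                "auc_internal": res.auc,
                "n_strata": res.n_strata_used,
            }
        )
    # full-data models for external validation
    full_models = fit_model_series(cohort_qc, efp_grid)
    for mdl in full_models:
        mdl.to_tsv(out / f"model_efp{mdl.efp_bound}.tsv")
    manifest["timings_s"]["risk"] = round(time.time() - t0, 2)

    # --- external validation ------------------------------------------------
    t0 = _stage("external")
    ext = cfg["external_cohort"]
    ec = cfg["cohort"]
    ext_spec = ArchitectureSpec(
        m=ec["m"], m_causal=ec["m_causal"], h2_l=ec["h2_l"], K=ec["K"],
        seed=cfg.stage_seed("external"),
    )
    ext_cohort = simulate_cohort(
        ext_spec, ext["n_case"], ext["n_control"], template=cohort_qc
    )
    ext_strata = default_strata(ext_cohort.samples)
    for row, mdl in zip(rows, full_models):
        sc = predict_scores(mdl, ext_cohort)
        row["auc_external"] = covariate_adjusted_auc(sc, ext_cohort.status, ext_strata).auc
        row["snps_full"] = mdl.size
    pd.DataFrame(rows).to_csv(out / "risk_auc.tsv", sep="\t", index=False)
    manifest["timings_s"]["external"] = round(time.time() - t0, 2)

    # --- family simulation ---------------------------------------------------
    t0 = _stage("family")
    fam = cfg["family"]
    ped = build_default_pedigree(fam["children"])
    draws = simulate_families(
        ped, fam["h2"], cfg["liability"]["K"], fam["n_families"], seed=cfg.stage_seed("family")
    )
    res_full = sporadic_proportion(draws, FULL_RELATIVE_SET)
    res_fd = sporadic_proportion(draws, FIRST_DEGREE_SET)
    pd.DataFrame(
        [
            {"relative_set": "full", "proportion": res_full.proportion,
             "ci_low": res_full.ci_low, "ci_high": res_full.ci_high, "n": res_full.n_families},
            {"relative_set": "parent_sibling", "proportion": res_fd.proportion,
             "ci_low": res_fd.ci_low, "ci_high": res_fd.ci_high, "n": res_fd.n_families},
        ]
    ).to_csv(out / "sporadic.tsv", sep="\t", index=False)
    manifest["timings_s"]["family"] = round(time.time() - t0, 2)

    # --- liability conversions ------------------------------------------------
    liability_conversion_table(cfg["liability"]["K"]).to_csv(
        out / "liability_conversions.tsv", sep="\t", index=False
    )
    for stage in ("external", "risk", "auc", "family"):
        manifest["stage_seeds"][stage] = cfg.stage_seed(stage)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def make_fixtures(out_dir: str | Path, seed: int = 20_240_101) -> Path:
    """Small deterministic datasets exercising every input format."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = ArchitectureSpec(m=120, m_causal=20, h2_l=0.4, K=0.05, seed=seed)
    cohort = simulate_cohort(spec, 60, 240)
    cohort = inject_platform_artifacts(cohort, 0.3, (0.01, 0.04), seed=seed + 1)
    write_cohort(cohort, out / "cohort", vcf=True)
    pd.DataFrame(
        {
            "zygosity": ["MZ", "DZ"],
            "n_double_concordant": [12, 2],
            "n_single_concordant": [30, 10],
            "n_discordant": [158, 188],
        }
    ).to_csv(out / "twin_counts.tsv", sep="\t", index=False)
    truth = cohort.snps.loc[cohort.snps["true_beta"] != 0.0]
    pd.DataFrame(
        {
            "snp": truth["snp_id"],
            "risk_allele": truth["allele_minor"],
            "OR": np.exp(truth["true_beta"]).round(3),
        }
    ).to_csv(out / "or_table.tsv", sep="\t", index=False)
    return out
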