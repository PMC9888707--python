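"""End-to-end analysis pipeline and run manifest.

Chains the stages: phenotype derivation -> genotype QC and variant
qualification -> burden construction -> association testing (total burden,
per-gene known and exome-wide scans with separate FDR, per-degree logistic
contrasts, Fisher carrier tests, common-variant GWAS) -> polygenic / burden
score evaluation.  Configuration is a plain YAML file whose keys mirror the
CLI flags; every analysis threshold appears as a named key with the study
default.  Identical config + seed yields identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from hlburden import assoc, burden as burden_mod, phenotype as phen_mod, qualify as qual_mod, scores
from hlburden.io import read_cohort, read_table, read_vcf, write_table

log = logging.getLogger("hlburden")

DEFAULT_CONFIG = {
    "seed": 0,
    "phenotype": {"phecode": "389", "exam": "latest"},
    "qualification": {
        "gnomad_af_max": 0.001,
        "cohort_af_max": 0.01,
        "revel_min": 0.6,
        "min_depth": 7,
        "min_het_alt_fraction": 0.15,
    },
    "association": {
        "n_pcs": 20,
        "known_case_carrier_threshold": 0,
        "novel_case_carrier_threshold": 25,
        "lambda_max": 1.05,
        "n_perms": 3,
        "calibrate": False,
    },
    "gwas": {"maf_min": 0.01, "rsq_min": 0.30},
    "prs": {"bootstrap": 200, "top_quantile": 0.90, "hl_threshold": 2},
}


def load_config(path) -> dict:
    """Load a YAML pipeline configuration, filling defaults."""
    with open(path) as f:
        user = yaml.safe_load(f) or {}
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def derive_phenotypes(audiograms, phecodes, individuals, phecode="389", exam="latest"):
    """Stage 1: hybrid degree-HL table, binary labels and the misclassification check."""
    phenotypes = phen_mod.assign_phenotype(audiograms, phecodes, individuals, phecode=phecode, exam=exam)
    labels = phen_mod.binarize_case_control(phenotypes)
    status = phen_mod.phecode_status_table(phecodes, individuals, phecode=phecode)
    misclass = phen_mod.misclassification_table(phenotypes, status)
    log.info(
        "phenotyping: %d individuals, %d included (%d audiogram, %d phecode-control), %d cases",
        len(phenotypes),
        int(phenotypes["included"].sum()),
        int((phenotypes["source"] == "audiogram").sum()),
        int((phenotypes["source"] == "phecode-control").sum()),
        int((labels == True).sum()),  # noqa: E712
    )
    return phenotypes, labels, misclass


def qualify_stage(G, depth, alt_reads, annotations, qc_cfg):
    """Stage 2: genotype QC, cohort AF and variant qualification."""
    if depth is not None and alt_reads is not None:
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(depth > 0, alt_reads / np.maximum(depth, 1), 0.0)
        G, keep = qual_mod.apply_genotype_qc(
            G, depth, frac, min_depth=qc_cfg["min_depth"], min_het_alt_fraction=qc_cfg["min_het_alt_fraction"]
        )
    else:
        keep = np.ones(G.shape[1], bool)
    ann = annotations.reset_index(drop=True).loc[keep].reset_index(drop=True)
    G = G[:, keep]
    af = qual_mod.cohort_allele_frequency(G)
    config = qual_mod.QualificationConfig(
        gnomad_af_max=qc_cfg["gnomad_af_max"],
        cohort_af_max=qc_cfg["cohort_af_max"],
        revel_min=qc_cfg["revel_min"],
    )
    qualified = qual_mod.qualify_variants(ann, af, config)
    log.info(
        "qualification: %d variants after QC (of %d), %d qualify (%d ClinVar-pathogenic)",
        int(keep.sum()),
        len(keep),
        len(qualified),
        int(qualified["clinvar_pathogenic"].sum()),
    )
    return G, ann, qualified


def burden_stage(G, ann, qualified, individual_ids, gene_set):
    """Stage 3: per-gene burden matrix and the study's variant-subset totals."""
    burdens = burden_mod.gene_burden(G, ann["variant_id"].tolist(), qualified, individual_ids)
    known = set(gene_set["gene_id"])
    known_cols = [g for g in burdens.columns if g in known]
    path, rest = qual_mod.clinvar_partition(qualified)
    subsets = {
        "all": qualified,
        "clinvar": path,
        "non_clinvar": rest,
        "DFNA": qualified[qualified["gene_id"].isin(gene_set.loc[gene_set["inheritance_class"] == "DFNA", "gene_id"])],
        "DFNB": qualified[qualified["gene_id"].isin(gene_set.loc[gene_set["inheritance_class"] == "DFNB", "gene_id"])],
        "DFNA+B": qualified[
            qualified["gene_id"].isin(gene_set.loc[gene_set["inheritance_class"] == "DFNA+B", "gene_id"])
        ],
    }
    totals = {}
    for name, qual_sub in subsets.items():
        sub_b = burden_mod.gene_burden(G, ann["variant_id"].tolist(), qual_sub, individual_ids)
        totals[name] = burden_mod.total_burden(sub_b, known_cols if name in ("all", "clinvar", "non_clinvar") else None)
    log.info("burden: %d genes with qualifying variants (%d known)", burdens.shape[1], len(known_cols))
    return burdens, totals, known_cols


def association_stage(burdens, totals, known_cols, phenotypes, labels, covariates, cfg, seed=0):
    """Stage 4: total-burden tests, per-gene scans with separate FDR, degree contrasts, Fisher tests."""
    phen = phenotypes[phenotypes["included"]].set_index("individual_id")
    cov = covariates.set_index("individual_id").loc[phen.index]
    complete = cov[["sex", "age"] + [f"PC{i}" for i in range(1, cfg["n_pcs"] + 1)]].notna().all(axis=1)
    phen, cov = phen[complete.to_numpy()], cov[complete.to_numpy()]
    design = assoc.build_covariates(cov, n_pcs=cfg["n_pcs"])
    y = phen["degree_hl"].astype(float).to_numpy()
    ids = phen.index

    total_rows = []
    for name, tot in totals.items():
        x = tot.reindex(ids).to_numpy(float)
        if np.ptp(x) == 0:
            continue
        res = assoc.linear_test(y, x, design)
        total_rows.append({"subset": name, **res})
    total_results = pd.DataFrame(total_rows)

    B = burdens.reindex(ids)
    lab = labels.reindex(ids)
    summary = burden_mod.carrier_summary(B, lab)
    known_summary = summary[summary["gene_id"].isin(known_cols)]
    novel_summary = summary[~summary["gene_id"].isin(known_cols)]

    def scan(summary_df, threshold):
        genes = burden_mod.filter_genes_by_case_carriers(summary_df, threshold)
        if not genes:
            return pd.DataFrame(columns=["unit", "beta", "se", "t", "p", "n", "q"]), np.nan
        res = assoc.linear_scan(y, B[genes].to_numpy(float), design, names=genes)
        res = res.merge(summary_df.rename(columns={"gene_id": "unit"}), on="unit", how="left")
        res["q"] = assoc.bh_adjust(np.nan_to_num(res["p"].to_numpy(), nan=1.0))
        finite = res["p"].dropna()
        lam = assoc.genomic_lambda(finite) if len(finite) else np.nan
        return res.sort_values("p").reset_index(drop=True), lam

    known_res, lam_known = scan(known_summary, cfg["known_case_carrier_threshold"])
    novel_res, lam_novel = scan(novel_summary, cfg["novel_case_carrier_threshold"])
    log.info(
        "association: %d known-gene tests (lambda=%.3f), %d exome-wide tests (lambda=%.3f)",
        len(known_res), lam_known, len(novel_res), lam_novel,
    )

    strata = {k: totals[k].reindex(ids) for k in ("all", "clinvar", "non_clinvar") if k in totals}
    degree_res = assoc.degree_level_effects(phenotypes[phenotypes["included"] & phenotypes["individual_id"].isin(ids)], strata, design.set_axis(ids, axis=0))

    fisher_rows = []
    is_case = (lab == True).to_numpy()  # noqa: E712
    is_ctrl = (lab == False).to_numpy()  # noqa: E712
    for name, tot in totals.items():
        carrier = tot.reindex(ids).to_numpy(float) >= 1
        table = [
            [int((carrier & is_case).sum()), int((~carrier & is_case).sum())],
            [int((carrier & is_ctrl).sum()), int((~carrier & is_ctrl).sum())],
        ]
        fisher_rows.append(
            {
                "subset": name,
                "case_carriers": table[0][0],
                "case_noncarriers": table[0][1],
                "control_carriers": table[1][0],
                "control_noncarriers": table[1][1],
                "p": assoc.fisher_carrier_test(table),
            }
        )
    fisher_results = pd.DataFrame(fisher_rows)

    calibration = None
    if cfg.get("calibrate"):
        def runner(threshold, y_perm):
            genes = burden_mod.filter_genes_by_case_carriers(novel_summary, int(threshold))
            if not genes:
                return np.array([])
            return assoc.linear_scan(y_perm, B[genes].to_numpy(float), design)["p"].to_numpy()

        calibration = assoc.permutation_calibration(
            runner, y, start=0, increment=5, stop=50,
            lambda_max=cfg["lambda_max"], n_perms=cfg["n_perms"], seed=seed,
        )

    return {
        "total": total_results,
        "known": known_res,
        "novel": novel_res,
        "lambda_known": lam_known,
        "lambda_novel": lam_novel,
        "degree": degree_res,
        "fisher": fisher_results,
        "calibration": calibration,
        "ids": ids,
        "design": design,
        "y": y,
    }


def run_pipeline(config: dict | str, output_dir) -> dict:
    """Execute the full analysis and write result tables plus a run manifest."""
    if not isinstance(config, dict):
        config = load_config(config)
    t0 = time.time()
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    inputs = config["inputs"]

    if "cohort_dir" in inputs:
        data = read_cohort(inputs["cohort_dir"])
        G, variants = data["rare_genotypes"], data["rare_variants"]
        depth, alt_reads = data["rare_depth"], data["rare_alt_reads"]
        samples = data["vcf_samples"]
        annotations = data["annotations"]
        covariates, audiograms, phecodes = data["covariates"], data["audiograms"], data["phecodes"]
        dosages, common_variants = data["common_dosages"], data["common_variants"]
        weights = data["prs_weights"]
    else:
        G, variants, samples, depth, alt_reads = read_vcf(inputs["vcf"])
        annotations = read_table(inputs["annotations"], "annotations")
        covariates = read_table(inputs["covariates"], "covariates")
        audiograms = read_table(inputs["audiograms"], "audiograms")
        phecodes = read_table(inputs["phecodes"], "phecodes")
        dosages = pd.read_csv(inputs["common_dosages"], sep="\t", dtype={"individual_id": str}).drop(
            columns=["individual_id"]
        ).to_numpy(float)
        common_variants = read_table(inputs["common_variants"], "common_variants")
        weights = read_table(inputs["prs_weights"], "weights")
    gene_set = (
        read_table(inputs["gene_set"], "gene_set") if inputs.get("gene_set") else burden_mod.load_known_genes()
    )
    # annotation rows must align with VCF records
    ann = annotations.set_index("variant_id").loc[variants["variant_id"]].reset_index()

    counts = {}
    phenotypes, labels, misclass = derive_phenotypes(
        audiograms, phecodes, covariates["individual_id"],
        phecode=config["phenotype"]["phecode"], exam=config["phenotype"]["exam"],
    )
    counts["individuals"] = len(covariates)
    counts["included"] = int(phenotypes["included"].sum())
    write_table(phenotypes, out / "phenotypes.tsv")
    write_table(misclass, out / "misclassification.tsv")

    Gq, annq, qualified = qualify_stage(G, depth, alt_reads, ann, config["qualification"])
    counts["variants"] = len(ann)
    counts["qualified_variants"] = len(qualified)
    write_table(qualified, out / "qualified_variants.tsv")

    burdens, totals, known_cols = burden_stage(Gq, annq, qualified, covariates["individual_id"], gene_set)
    counts["genes_with_qualifying_variants"] = burdens.shape[1]
    write_table(burdens.reset_index(), out / "burden_matrix.tsv")

    res = association_stage(burdens, totals, known_cols, phenotypes, labels, covariates, config["association"], seed=seed)
    write_table(res["total"], out / "total_burden_results.tsv")
    write_table(res["known"], out / "known_gene_results.tsv")
    write_table(res["novel"], out / "novel_gene_results.tsv")
    write_table(res["degree"], out / "degree_effects.tsv")
    write_table(res["fisher"], out / "fisher_carrier_tests.tsv")
    if res["calibration"] is not None:
        write_table(res["calibration"].to_frame(), out / "calibration.tsv")
    counts["known_gene_tests"] = len(res["known"])
    counts["novel_gene_tests"] = len(res["novel"])

    ids, design, y = res["ids"], res["design"], res["y"]
    id_pos = pd.Index(covariates["individual_id"]).get_indexer(ids)
    gwas_res = assoc.gwas(
        dosages[id_pos], common_variants, y, design,
        maf_min=config["gwas"]["maf_min"], rsq_min=config["gwas"]["rsq_min"],
    )
    counts["gwas_variants"] = len(gwas_res)
    gwas_finite = gwas_res["p"].dropna() if len(gwas_res) else pd.Series(dtype=float)
    lam_gwas = assoc.genomic_lambda(gwas_finite) if len(gwas_finite) else np.nan
    write_table(gwas_res, out / "gwas_results.tsv")
    qq = gwas_res["p"].dropna().sort_values().to_numpy()
    if qq.size:
        write_table(
            pd.DataFrame(
                {
                    "expected_neglog10": -np.log10((np.arange(1, qq.size + 1) - 0.5) / qq.size),
                    "observed_neglog10": -np.log10(qq),
                }
            ),
            out / "gwas_qq.tsv",
        )

    prs_scores, prs_report = scores.apply_prs(dosages[id_pos], common_variants, weights)
    hl_total = totals["all"].reindex(ids).to_numpy(float)
    strata = {"all": np.ones(len(ids), bool)}
    anc = covariates.set_index("individual_id").loc[ids, "ancestry"]
    for a in anc.unique():
        strata[str(a)] = (anc == a).to_numpy()
    has_aud = phenotypes.set_index("individual_id").loc[ids, "source"].eq("audiogram").to_numpy()
    strata["audiogram"] = has_aud
    for a in anc.unique():
        strata[f"audiogram:{a}"] = has_aud & (anc == a).to_numpy()
    eval_table = scores.stratified_evaluation(
        y, design, {"PRS": prs_scores, "HL-burden": hl_total}, strata,
        B=int(config["prs"]["bootstrap"]), seed=seed,
    )
    write_table(eval_table, out / "score_evaluation.tsv")
    try:
        strat = scores.top_decile_or(
            prs_scores, y, score_b=hl_total,
            q=config["prs"]["top_quantile"], hl_threshold=config["prs"]["hl_threshold"],
        )
    except ValueError:
        strat = None

    manifest = {
        "tool": "hlburden",
        "version": __import__("hlburden").__version__,
        "seed": seed,
        "config_hash": hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest(),
        "counts": counts,
        "lambda": {"known": res["lambda_known"], "novel": res["lambda_novel"], "gwas": float(lam_gwas)},
        "prs_matching": prs_report,
        "top_decile": strat,
        "elapsed_s": round(time.time() - t0, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    log.info("pipeline complete in %.1fs", manifest["elapsed_s"])
    return manifest
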