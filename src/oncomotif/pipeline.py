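"""End-to-end orchestration: simulate -> screen -> motif -> targets ->
signature -> network, each stage writing its outputs under a subdirectory."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import cohort as cohort_mod
from . import motif as motif_mod
from . import network as network_mod
from . import screen as screen_mod
from . import simulate as sim
from . import targets as targets_mod
from .io import RunConfig, log, write_matrix


def _stage_dir(out_dir: Path, name: str) -> Path:
    d = out_dir / name
    d.mkdir(parents=True, exist_ok=True)
    return d


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute every stage on freshly simulated data; returns a summary dict.

    A failure in any stage propagates with the stage name in the log; outputs
    written so far are left in place for inspection.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "resolved_config.yaml")
    seeds = config.sim_seeds()
    summary: dict = {"seed": config.seed, "stage_seeds": seeds}

    # --- simulate ---------------------------------------------------------
    log.info("stage=simulate seed=%s", config.seed)
    d = _stage_dir(out_dir, "simulate")
    screen_cfg = sim.ScreenSimConfig(**{**config.screen_sim, "seed": seeds["screen_sim"]})
    table, catalogue, screen_truth = sim.generate_screen(screen_cfg)
    write_matrix(table.counts, d / "screen_counts.tsv")
    catalogue.to_fasta(d / "mirna_catalogue.fasta")
    screen_truth.to_json(d / "screen_truth.json")

    omics_cfg = sim.OmicsSimConfig(**{**config.omics_sim, "seed": seeds["omics_sim"]})
    mrna, protein, predictions, omics_truth = sim.generate_omics(omics_cfg)
    write_matrix(mrna, d / "mrna_matrix.tsv")
    write_matrix(protein, d / "protein_matrix.tsv")
    predictions.to_frame().to_csv(d / "prediction_counts.tsv", sep="\t")
    omics_truth.to_json(d / "omics_truth.json")

    cohort_cfg = sim.CohortSimConfig(**{**config.cohort_sim, "seed": seeds["cohort_sim"]})
    dataset, cohort_truth = sim.generate_cohort(cohort_cfg)
    write_matrix(dataset.mirna_expr.T, d / "cohort_mirna.tsv")
    write_matrix(dataset.mrna_expr.T, d / "cohort_mrna.tsv")
    dataset.metadata.to_csv(d / "cohort_metadata.tsv", sep="\t")
    cohort_truth.to_json(d / "cohort_truth.json")

    # --- screen -----------------------------------------------------------
    log.info("stage=screen")
    d = _stage_dir(out_dir, "screen")
    res = screen_mod.analyze_screen(table, **config.screen)
    res.to_csv(d / "enrichment_results.tsv", sep="\t")
    conds = table.conditions
    enr_col = f"class_{conds[1]}_vs_{conds[0]}"
    dep_col = f"class_{conds[2]}_vs_{conds[1]}"
    enriched = res.index[res[enr_col] == "enriched"].tolist()
    depleted = res.index[res[dep_col] == "depleted"].tolist()
    dual = screen_mod.intersect_hits(enriched, depleted)
    summary["screen"] = {
        "n_filtered": int(res["passed_filter"].sum()),
        "n_enriched": len(enriched),
        "n_depleted": len(depleted),
        "n_dual": len(dual),
    }

    # --- motif ------------------------------------------------------------
    log.info("stage=motif")
    d = _stage_dir(out_dir, "motif")
    hits = sorted(set(enriched) | set(depleted))
    if hits:
        motifs = motif_mod.find_shared_motifs(hits, catalogue, k=config.motif["k"])
        motifs.to_csv(d / "motif_table.tsv", sep="\t", index=False)
        top_motif = motifs.iloc[0]["motif"]
        p_enr = motif_mod.motif_enrichment(top_motif, hits, catalogue)
        family = motif_mod.assign_seed_family(catalogue, top_motif)
        motif_mod.family_to_frame(family).to_csv(
            d / "seed_family.tsv", sep="\t", index=False
        )
        summary["motif"] = {
            "top_motif": str(top_motif),
            "family_size": len(family),
            "enrichment_p": p_enr,
        }
    else:
        top_motif = None
        summary["motif"] = {"top_motif": None}

    # --- targets ----------------------------------------------------------
    log.info("stage=targets")
    d = _stage_dir(out_dir, "targets")
    mrna_diff = targets_mod.differential_table(*targets_mod.split_arms(mrna))
    if protein is not None and len(protein):
        prot_diff = targets_mod.differential_table(*targets_mod.split_arms(protein))
    else:
        prot_diff = None
        log.warning("stage=targets protein matrix absent; mRNA-only evidence")
    evidence = targets_mod.build_evidence_table(mrna_diff, prot_diff, predictions)
    evidence = targets_mod.call_putative_targets(evidence, **config.targets)
    evidence.to_csv(d / "evidence_table.tsv", sep="\t")
    curves, shifts = targets_mod.ecdf_shift(evidence["mrna_log2fc"], evidence["stratum"])
    shifts.to_csv(d / "ecdf_shift.tsv", sep="\t")
    for stratum, curve in curves.items():
        curve.to_csv(d / f"ecdf_{stratum.replace('>', 'gt')}.tsv", sep="\t", index=False)
    putative = evidence.index[evidence["putative_target"]].tolist()
    summary["targets"] = {"n_putative": len(putative)}

    # --- signature --------------------------------------------------------
    log.info("stage=signature")
    d = _stage_dir(out_dir, "signature")
    sums = cohort_mod.sum_family_expression(dataset.mirna_expr, dataset.family_ids)
    tumor_sums = sums[dataset.metadata["is_tumor"] == 1]
    high, low = cohort_mod.percentile_groups(tumor_sums, pct=config.signature["pct"])
    signature = cohort_mod.derive_signature(
        dataset.mrna_expr,
        high,
        low,
        fdr_threshold=config.signature["fdr_threshold"],
        lfc_threshold=config.signature["lfc_threshold"],
    )
    signature.to_csv(d / "signature.tsv", sep="\t")
    sig_genes = signature.index[signature["selected"]].tolist()
    if len(sig_genes) >= 2:
        labels, _ = cohort_mod.hierarchical_cluster(dataset.mrna_expr[sig_genes])
    else:
        labels = pd.Series("cluster_low", index=dataset.mrna_expr.index, name="cluster")
        log.warning("stage=signature too few signature genes for clustering")
    labels.to_frame().to_csv(d / "clusters.tsv", sep="\t")

    tumors = dataset.metadata.index[dataset.metadata["is_tumor"] == 1]
    _, wil_p = cohort_mod.genotype_association(
        sums[tumors], dataset.metadata.loc[tumors, "TP53_mut"]
    )
    if labels[tumors].nunique() == 2:
        surv = cohort_mod.km_logrank(
            dataset.metadata.loc[tumors, "rfs_time"],
            dataset.metadata.loc[tumors, "rfs_event"],
            labels[tumors],
        )
        for g, curve in surv["curves"].items():
            curve.to_csv(d / f"km_{g}.tsv", sep="\t", index=False)
        cox = cohort_mod.cox_regression(
            dataset.metadata.loc[tumors, "rfs_time"],
            dataset.metadata.loc[tumors, "rfs_event"],
            pd.DataFrame(
                {
                    "cluster": labels[tumors],
                    "TP53_mut": dataset.metadata.loc[tumors, "TP53_mut"].astype(str),
                }
            ),
        )
        cox.to_csv(d / "cox_summary.tsv", sep="\t")
    else:
        surv = {"chi2": float("nan"), "p": float("nan")}
        log.warning("stage=signature single cluster; survival tests skipped")
    summary["signature"] = {
        "n_signature_genes": len(sig_genes),
        "wilcoxon_tp53_p": wil_p,
        "logrank_p": surv["p"],
    }
    with open(d / "survival_summary.json", "w") as fh:
        json.dump(
            {"logrank_chi2": surv["chi2"], "logrank_p": surv["p"]}, fh, indent=1
        )

    # --- network ----------------------------------------------------------
    log.info("stage=network")
    d = _stage_dir(out_dir, "network")
    profile = network_mod.correlate_genes(
        sums, dataset.mrna_expr, log_scale=config.network["log_scale"]
    )
    profile.to_csv(d / "correlation_profile.tsv", sep="\t")
    candidates = [g for g in cohort_cfg.ts_genes if g in profile.index]
    inverse = network_mod.call_inverse_targets(
        profile, candidates, threshold=config.network["threshold"]
    )
    summary["network"] = {
        "n_ts_inverse": len(inverse),
        "median_family_rpm": float(sums.median()),
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=str)
    return summary
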