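"""End-to-end orchestration: simulate/load -> preprocess -> normalise ->
differential expression -> mitochondrial correction -> profiles.

Every stage writes its outputs as TSV into the run directory and records
row/column counts in a manifest (JSON). All randomness flows through the
seeds recorded there, so re-running with the same config and seed
reproduces every numeric output bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diffexpr import (
    de_table,
    eb_moderate,
    fibre_contrast_samples,
    fit_linear_models,
    fusion_scheme,
    mds_coordinates,
    paired_design,
    paired_differences,
    training_contrast_samples,
)
from .io import (
    LOG2,
    PipelineConfig,
    QuantMatrix,
    ValidationError,
    functional_group_members,
    read_annotations,
    read_quant_matrix,
    write_quant_matrix,
    write_report_table,
)
from .mitonorm import (
    compare_before_after,
    compute_mpe,
    mean_mito_expression,
    mito_renormalise,
    mitochondrial_ids,
    mpe_summary,
)
from .normalise import log2_transform, normalise_chain
from .preprocess import filter_by_confidence, filter_missing, knn_impute
from .profiles import cluster_heatmap_order, group_delta_profile, zscore_scale
from .simulate import CohortParams, generate_cohort, write_cohort


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    config: dict
    seed: int
    version: str = __version__
    input_digests: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)
    output_digests: dict = field(default_factory=dict)

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def biological_design(sample_annot: pd.DataFrame) -> pd.DataFrame:
    """Fibre-type/timepoint/training dummy covariates (no intercept),
    indexed by sample id — the biology ComBat must not absorb."""
    annot = sample_annot.set_index("sample_id")
    return pd.DataFrame({
        "fibre_II": (annot["fibre_type"] == "II").astype(float),
        "post": (annot["timepoint"] == "POST").astype(float),
        "sit": (annot["training"] == "SIT").astype(float),
    })


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    seed: int | None = None,
    simulate: bool = True,
    cohort_params: CohortParams | None = None,
    matrix_path: str | Path | None = None,
    sample_path: str | Path | None = None,
    protein_path: str | Path | None = None,
) -> dict:
    """Run the full analysis and write all stage outputs plus a manifest.

    With ``simulate=True`` a synthetic cohort is generated from
    ``cohort_params`` (study-design defaults otherwise); with
    ``simulate=False`` the three input TSVs are read instead.
    Returns the in-memory results keyed by stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    manifest = RunManifest(config=dataclasses.asdict(config), seed=seed)
    results: dict = {}

    # ---- stage: input -----------------------------------------------------
    if simulate:
        matrix, sample_annot, protein_annot, truth = generate_cohort(
            cohort_params or CohortParams(), seed=seed
        )
        write_cohort(outdir / "cohort", matrix, sample_annot, protein_annot, truth)
        for name in ("quant_raw", "samples", "proteins", "truth"):
            manifest.input_digests[name] = _digest(outdir / "cohort" / f"{name}.tsv")
        results["truth"] = truth
    else:
        if not (matrix_path and sample_path and protein_path):
            raise ValidationError(
                "matrix, sample and protein paths are required without --simulate"
            )
        matrix = read_quant_matrix(matrix_path, scale="raw")
        sample_annot, protein_annot = read_annotations(
            sample_path, protein_path, matrix
        )
        for name, p in (("quant_raw", matrix_path), ("samples", sample_path),
                        ("proteins", protein_path)):
            manifest.input_digests[name] = _digest(Path(p))
    results["matrix_raw"] = matrix
    results["sample_annot"] = sample_annot
    results["protein_annot"] = protein_annot
    manifest.stage_counts["input"] = {
        "n_proteins": matrix.shape[0], "n_samples": matrix.shape[1],
        "n_missing": matrix.n_missing,
    }

    # ---- stage: preprocess ------------------------------------------------
    filtered, conf_report = filter_by_confidence(matrix, protein_annot)
    filtered, miss_report = filter_missing(filtered, config.max_missing_fraction)
    logged = log2_transform(filtered, zero_offset=config.log2_offset)
    imputed_log2 = knn_impute(logged, k=config.knn_k)
    complete_raw = imputed_log2.with_data(
        np.exp2(imputed_log2.data), scale="raw"
    )
    write_report_table(conf_report.to_frame(), outdir / "filter_confidence.tsv")
    write_report_table(miss_report.to_frame(), outdir / "filter_missing.tsv")
    write_quant_matrix(imputed_log2, outdir / "imputed_log2.tsv")
    manifest.stage_counts["preprocess"] = {
        "n_input": conf_report.n_input,
        "n_removed_confidence": conf_report.n_removed_confidence,
        "n_removed_contaminant": conf_report.n_removed_contaminant,
        "n_removed_unique_peptide": conf_report.n_removed_unique_peptide,
        "n_removed_missing": miss_report.n_removed_missing,
        "n_retained": miss_report.n_retained,
    }
    results["matrix_complete_raw"] = complete_raw
    results["filter_reports"] = (conf_report, miss_report)

    # ---- stage: normalise -------------------------------------------------
    covariates = biological_design(sample_annot) if config.combat_covariates else None
    normalised, factors, batch_model = normalise_chain(
        complete_raw, sample_annot,
        trim_m=config.trim_m, trim_a=config.trim_a,
        zero_offset=config.log2_offset, covariates=covariates,
    )
    write_quant_matrix(normalised, outdir / "normalised_log2.tsv")
    factor_table = pd.DataFrame({
        "sample_id": normalised.sample_ids,
        "sl_factor": factors.sl.loc[normalised.sample_ids].to_numpy(),
        "tmm_factor": factors.tmm.loc[normalised.sample_ids].to_numpy(),
    })
    write_report_table(factor_table, outdir / "normalisation_factors.tsv")
    manifest.stage_counts["normalise"] = {
        "tmm_reference": factors.reference,
        "n_batches": len(batch_model.batches),
    }
    results["matrix_normalised"] = normalised
    results["normalisation_factors"] = factors
    results["batch_model"] = batch_model

    # ---- stage: differential expression ----------------------------------
    pre = fibre_contrast_samples(sample_annot, timepoint="PRE")
    sub = normalised.subset_samples(list(pre["sample_id"]))
    cond = pre.set_index("sample_id")["fibre_type"]
    fit = eb_moderate(fit_linear_models(sub, paired_design(pre, cond, "II")))
    fibre_de = de_table(
        fit, alpha=config.de_alpha, lfc_display=config.lfc_display,
        label_up="higher_in_type_II", label_down="higher_in_type_I",
    )
    write_report_table(fibre_de, outdir / "de_fibre_PRE.tsv")
    results["fibre_de"] = fibre_de

    fusion_tables = {}
    for training in ("MICT", "SIT"):
        for fibre in ("I", "II"):
            cell = training_contrast_samples(sample_annot, training, fibre)
            cell_matrix = normalised.subset_samples(list(cell["sample_id"]))
            diffs = paired_differences(
                cell_matrix, cell,
                cell.set_index("sample_id")["timepoint"], "POST",
            )
            fus = fusion_scheme(
                diffs, n_perm=config.n_permutations, seed=seed,
            )
            fusion_tables[(training, fibre)] = fus
            write_report_table(fus, outdir / f"fusion_{training}_type{fibre}.tsv")
    results["fusion"] = fusion_tables

    mds = mds_coordinates(normalised)
    write_report_table(mds.rename_axis("sample_id").reset_index(),
                       outdir / "mds_coordinates.tsv")
    results["mds"] = mds
    manifest.stage_counts["diffexpr"] = {
        "n_fibre_de_significant": int(fibre_de["significant"].sum()),
        "fusion_cells": len(fusion_tables),
    }

    # ---- stage: mitochondrial correction ----------------------------------
    sl_matrix = complete_raw.with_data(
        complete_raw.data * factors.sl, scale="raw"
    )
    mpe = compute_mpe(sl_matrix, protein_annot)
    write_report_table(mpe.rename_axis("sample_id").reset_index(),
                       outdir / "mpe.tsv")
    write_report_table(mpe_summary(mpe, sample_annot), outdir / "mpe_summary.tsv")
    mito_ids = [
        p for p in mitochondrial_ids(protein_annot)
        if p in normalised.data.index
    ]
    mme_table, mme_test = mean_mito_expression(
        normalised, protein_annot, sample_annot, timepoint="PRE"
    )
    write_report_table(mme_table, outdir / "mean_mito_expression.tsv")

    mito_corrected, mito_factors, mito_batch = mito_renormalise(
        complete_raw, protein_annot, sample_annot,
        trim_m=config.trim_m, trim_a=config.trim_a,
        zero_offset=config.log2_offset, covariates=covariates,
    )
    write_quant_matrix(mito_corrected, outdir / "mito_corrected_log2.tsv")

    pre_cond = pre.set_index("sample_id")["fibre_type"]
    before = fibre_de[fibre_de["protein_id"].isin(mito_ids)].reset_index(drop=True)
    sub_after = mito_corrected.subset_samples(list(pre["sample_id"]))
    fit_after = eb_moderate(
        fit_linear_models(sub_after, paired_design(pre, pre_cond, "II"))
    )
    after = de_table(
        fit_after, alpha=config.de_alpha, lfc_display=config.lfc_display,
        label_up="higher_in_type_II", label_down="higher_in_type_I",
    )
    comparison = compare_before_after(before, after)
    write_report_table(comparison.transitions, outdir / "mito_de_transitions.tsv")
    manifest.stage_counts["mitonorm"] = {
        "n_mito_proteins": len(mito_ids),
        "mme_paired_p": mme_test["p"],
        "n_sig_before": comparison.n_before,
        "n_sig_after": comparison.n_after,
        "n_sig_overlap": comparison.n_overlap,
    }
    results["mpe"] = mpe
    results["mean_mito_expression"] = (mme_table, mme_test)
    results["matrix_mito_corrected"] = mito_corrected
    results["mito_comparison"] = comparison

    # ---- stage: profiles --------------------------------------------------
    groups = functional_group_members(protein_annot)
    profile_frames = []
    for training in ("MICT", "SIT"):
        for fibre in ("I", "II"):
            cell = sample_annot[
                (sample_annot["training"] == training)
                & (sample_annot["fibre_type"] == fibre)
            ]
            z_cell = zscore_scale(normalised, list(cell["sample_id"]))
            profile_frames.append(
                group_delta_profile(z_cell, groups, cell)
            )
    profile = pd.concat(profile_frames, ignore_index=True)
    if len(profile):
        from .diffexpr import bh_adjust  # family-wide readjustment

        ok = profile["p"].notna().to_numpy()
        padj = np.full(len(profile), np.nan)
        if ok.any():
            padj[ok] = bh_adjust(profile.loc[ok, "p"].to_numpy())
        profile["p_adj"] = padj
    write_report_table(profile, outdir / "group_profiles.tsv")
    results["profiles"] = profile

    z_pre = zscore_scale(normalised, list(pre["sample_id"]))
    order = cluster_heatmap_order(z_pre)
    pd.DataFrame({"sample_id": order["col_order"]}).to_csv(
        outdir / "heatmap_sample_order.tsv", sep="\t", index=False
    )
    manifest.stage_counts["profiles"] = {
        "n_groups": len(groups),
        "n_profile_rows": len(profile),
    }
    results["heatmap_order"] = order

    for path in sorted(outdir.glob("*.tsv")):
        manifest.output_digests[path.name] = _digest(path)
    manifest.write(outdir / "manifest.json")
    results["manifest"] = manifest
    return results
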