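"""End-to-end orchestration: simulate -> QC -> classify -> glands ->
features -> stats, with deterministic file outputs.

Every stage logs its filter counts and fit diagnostics through the module
logger; all output tables are written with a fixed float format so repeated
runs from the same seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_qc, synthetic, classifier, glands, features, stats

log = logging.getLogger("glandscape")


@dataclass
class PipelineConfig:
    """Configuration for a full synthetic-cohort run."""

    n_patients: int = 8
    cores_per_patient: int = 1
    seed: int = 0
    hazard_ratio_far: float = 2.0       # hazard multiplier past the feature cutoff
    hazard_cutoff_px: float = 55.0
    qc: io_qc.QCConfig = field(default_factory=io_qc.QCConfig)
    em: classifier.EMConfig = field(default_factory=classifier.EMConfig)
    core: synthetic.SimCoreConfig = field(default_factory=synthetic.SimCoreConfig)
    ratio_threshold: float = glands.DEFAULT_RATIO_THRESHOLD
    band_half_width: float = glands.DEFAULT_BAND_HALF_WIDTH
    curve_df: int = glands.DEFAULT_CURVE_DF
    alpha_px: float = 30.0
    md_min_points: int = 5
    n_perm: int = 10_000


def classify_core(table: io_qc.CellTable, mask: io_qc.GlandMask,
                  cfg: PipelineConfig) -> tuple[io_qc.CellTable, pd.DataFrame, dict]:
    """QC + normalize + mixture classification + gland stage for one core.

    Returns the fully labeled table (cell_label, phenotype, gland_id), the
    per-gland frame, and a diagnostics dict.
    """
    qc_table, report = io_qc.apply_qc(table, cfg.qc)
    log.info("core %s: QC removed %d/%d cells", table.core_id,
             report.n_removed, report.n_input)
    norm = io_qc.normalize_log2(qc_table)
    labeled, fits = classifier.label_ce_nce(norm, em_cfg=cfg.em)
    for m, fit in fits.items():
        log.info("core %s: %s mixture converged=%s iters=%d means=%s",
                 table.core_id, m, fit.converged, fit.n_iterations,
                 np.round(fit.means, 3).tolist())

    # immune phenotyping from per-marker mixture gating on all cells
    calls = {}
    for m in io_qc.IMMUNE_MARKERS:
        vals = labeled.df[m].to_numpy()
        try:
            fit = classifier.fit_gmm_em(vals, cfg.em)
            calls[m] = classifier.classify_positive(vals, fit)
        except classifier.FitError:
            calls[m] = np.zeros(len(labeled.df), dtype=np.int8)
    labeled.df["phenotype"] = classifier.assign_immune_phenotypes(
        pd.DataFrame(calls, index=labeled.df.index)).to_numpy()
    # epithelial cells are never immune-phenotyped
    labeled.df.loc[labeled.df["compartment"] == "epithelial", "phenotype"] = "other"

    final, gland_df, curves, _ = glands.classify_glands(
        labeled, mask, ratio_threshold=cfg.ratio_threshold,
        band_half_width=cfg.band_half_width, curve_df=cfg.curve_df)
    diag = {"qc": report.removed_per_rule,
            "fits": {m: f.to_dict() for m, f in fits.items()},
            "n_glands": len(gland_df),
            "n_nce_glands": int((gland_df["gland_label"] == "N-CE").sum())}
    return final, gland_df, diag


def run_all(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run the full synthetic-cohort pipeline and write all outputs.

    Writes per-core cell tables and masks, the gland table, patient feature
    table, clinical table, and a stats JSON into ``outdir``. Deterministic:
    the same config (including seed) yields byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def link(f: float) -> float:
        return cfg.hazard_ratio_far if f >= cfg.hazard_cutoff_px else 1.0

    cores, clinical, truths = synthetic.simulate_cohort(
        cfg.n_patients, cfg.cores_per_patient, hazard_link=link,
        core_config=cfg.core, seed=cfg.seed)

    core_feats = []
    gland_frames = []
    cell_frames = []
    for (table, mask), truth in zip(cores, truths):
        final, gland_df, _ = classify_core(table, mask, cfg)
        gland_df.insert(0, "core_id", table.core_id)
        gland_frames.append(gland_df)
        cdf = final.df.copy()
        cdf.insert(0, "core_id", table.core_id)
        cdf.insert(1, "patient_id", table.patient_id)
        cell_frames.append(cdf)
        core_feats.append(features.extract_core_features(
            final, mask, gland_df, alpha=cfg.alpha_px,
            min_points=cfg.md_min_points))

    cells = pd.concat(cell_frames, ignore_index=True)
    gland_table = pd.concat(gland_frames, ignore_index=True)
    pat = features.patient_feature_table(core_feats)
    merged = pat.merge(clinical, on="patient_id", how="inner")

    results: dict = {"n_patients": int(len(merged)),
                     "n_cores": len(cores),
                     "n_cells": int(len(cells))}

    # composition-by-grade test on final cell labels
    epi_stroma = cells[cells["cell_label"].isin(["CE", "N-CE", "stroma"])]
    grade_per_cell = epi_stroma["patient_id"].map(
        clinical.set_index("patient_id")["grade_group"])
    if grade_per_cell.nunique() >= 2:
        chi, p = stats.permutation_chisq(grade_per_cell,
                                         epi_stroma["cell_label"],
                                         n_perm=cfg.n_perm, seed=cfg.seed)
        results["composition_chisq"] = {"chisq": chi, "p": p}

    # AMACR: CE vs N-CE pooled permutation test + fold change
    epi = cells[cells["cell_label"].isin(["CE", "N-CE"])]
    ce_vals = epi.loc[epi["cell_label"] == "CE", io_qc.CANCER_MARKER]
    nce_vals = epi.loc[epi["cell_label"] == "N-CE", io_qc.CANCER_MARKER]
    if len(ce_vals) and len(nce_vals):
        stat, p = stats.permutation_diff_test(ce_vals, nce_vals,
                                              n_perm=cfg.n_perm, seed=cfg.seed)
        fold, l2 = stats.log_fold_change(2.0 ** ce_vals, 2.0 ** nce_vals)
        results["amacr"] = {"median_diff_log2": stat, "p": p,
                            "fold_change": fold, "log2_fold": l2}

    # KM / log-rank on median-dichotomized T-cell distances
    for feat, col in (("treg", "median_treg_distance_um"),
                      ("th", "median_th_distance_um")):
        v = merged[col].to_numpy()
        if np.isfinite(v).sum() >= 4 and merged["bcr_event"].any():
            try:
                split = stats.dichotomize_by_median(
                    v, merged["bcr_time_months"], merged["bcr_event"])
                km = stats.km_logrank(split)
                results[f"km_{feat}"] = {
                    "chisq": km["chisq"], "p": km["p"],
                    "median_cutoff_um": km["median_cutoff"],
                    "n_far": km["n_far"], "n_near": km["n_near"]}
            except (stats.StatTestError, stats.SplitError) as exc:
                log.warning("KM on %s skipped: %s", feat, exc)

    # write deterministic outputs
    cells_out = cells.copy()
    for col in ("qc_p63", "qc_CK5"):
        if col in cells_out.columns:
            cells_out[col] = cells_out[col].astype(int)
    cells_out.to_csv(outdir / "cells.csv", index=False,
                     float_format="%.8g", lineterminator="\n")
    gland_table.to_csv(outdir / "glands.csv", index=False,
                       float_format="%.8g", lineterminator="\n")
    pat.to_csv(outdir / "patient_features.csv", index=False,
               float_format="%.8g", lineterminator="\n")
    io_qc.write_clinical_table(clinical.drop(columns=["true_feature"]),
                               outdir / "clinical.csv")
    with open(outdir / "stats.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return results
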