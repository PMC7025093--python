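"""End-to-end pipeline orchestration.

Runs the screen analysis stage by stage — simulate (optional) -> QC ->
per-plate standardization -> outlier detection -> classifier training ->
single-cell classification -> strain summaries -> threshold calibration ->
mutant calling -> consensus -> report — persisting every intermediate as
delimited text in a run directory. All stochastic steps derive their seeds
from the single run seed, which is echoed in the run log.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from phenoscreen import classify, calls, outliers, qc, simulate
from phenoscreen.core_data import FeatureTable, default_taxonomy, write_feature_table
from phenoscreen.errors import ConfigurationError, PhenoscreenError

logger = logging.getLogger(__name__)


class StageError(PhenoscreenError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.time()
            try:
                out = fn(*args, **kwargs)
            except PhenoscreenError as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s finished in %.1fs", name, time.time() - t0)
            return out
        return wrapped
    return deco


def default_config(seed: int = 0) -> dict[str, Any]:
    """A small but complete synthetic-run configuration."""
    return {
        "seed": seed,
        "simulate": {
            "n_strains": 30,
            "marker": "vacuole",
            "n_features": 15,
            "separation": 6.0,
            "cells_per_field_mean": 20.0,
            "batch_shift_sd": 0.5,
            "n_replicates": 1,
        },
        "qc": {},
        "outliers": {"variance_target": 0.8, "nu": 0.5, "control_percentile": 20.0},
        "training": {"n_per_class": 60},
        "classifier": {"n_inits": 3, "epochs": 60},
        "calls": {},
    }


def call_mutants_from_predictions(
    preds: pd.DataFrame,
    good: pd.DataFrame,
    taxonomy,
    marker: str,
    control_strain: str = "WT",
    condition: str = "",
    screen_type: str = "",
    call_cfg: "calls.CallConfig | None" = None,
) -> tuple[pd.DataFrame, "calls.PenetranceThreshold"]:
    """Summarize strains from per-cell predictions and call mutants.

    Wild-type control wells are summarized per (plate, well) as replicate
    pseudo-strains for threshold calibration; the pooled wild-type cells form
    the background of the penetrance significance test.
    """
    call_cfg = call_cfg or calls.CallConfig()
    wt_class = taxonomy.wild_type_class[marker]
    merged = preds.merge(
        good[["cell_id", "strain_id", "allele_id", "plate_id", "well_id"]], on="cell_id"
    )
    mutant_summaries: list[calls.StrainSummary] = []
    for strain, grp in merged[merged["strain_id"] != control_strain].groupby("strain_id"):
        s = calls.summarize_strain(
            grp["assigned"], wt_class,
            {"strain_id": strain, "allele_id": grp["allele_id"].iloc[0],
             "marker": marker, "condition": condition, "screen_type": screen_type},
        )
        if s:
            mutant_summaries.append(s)
    wt_summaries: list[calls.StrainSummary] = []
    wt_cells = merged[merged["strain_id"] == control_strain]
    for (plate, well), grp in wt_cells.groupby(["plate_id", "well_id"]):
        s = calls.summarize_strain(
            grp["assigned"], wt_class,
            {"strain_id": f"WT:{plate}:{well}", "allele_id": "wt",
             "marker": marker, "condition": condition, "screen_type": screen_type},
        )
        if s:
            wt_summaries.append(s)

    pen_thr = calls.calibrate_penetrance_threshold(wt_summaries, marker, condition)
    k_wt = int((wt_cells["assigned"] != wt_class).sum())
    n_wt = len(wt_cells)
    aberrant = [c for c in taxonomy.classes_of(marker) if c != wt_class]
    spm_thresholds = {}
    for phen in aberrant:
        max_obs = max(
            (s.fraction(phen) for s in mutant_summaries + wt_summaries), default=0.0
        )
        spm_thresholds[phen] = calls.calibrate_spm_thresholds(
            wt_summaries, phen, condition, max_observed=max_obs
        )
    rows = []
    m_tests = len(mutant_summaries)
    for s in mutant_summaries:
        rec = calls.call_penetrance_mutant(
            s, pen_thr, call_cfg, wt_background=(k_wt, n_wt),
            m_tests=m_tests, wild_type_class=wt_class,
        )
        spm_flags = {p: calls.call_spm(s, spm_thresholds[p], call_cfg) for p in aberrant}
        rows.append(
            {
                "strain_id": s.strain_id,
                "gene_id": s.strain_id.rsplit("-", 1)[0],
                "allele_id": s.allele_id,
                **rec,
                "is_spm": any(f[0] for f in spm_flags.values()),
                "is_stringent_spm": any(f[1] for f in spm_flags.values()),
                **{f"frac_{p}": s.fraction(p) for p in aberrant},
            }
        )
    return pd.DataFrame(rows), pen_thr


def run_pipeline(cfg: Mapping[str, Any], outdir: str | Path) -> dict[str, Path]:
    """Execute the full synthetic-screen pipeline; return paths of outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if "seed" not in cfg:
        raise ConfigurationError("config field 'seed' is required")
    seed = int(cfg["seed"])
    paths: dict[str, Path] = {}
    log_records: dict[str, Any] = {"seed": seed, "stages": []}

    # --- simulate ---------------------------------------------------------
    sim_cfg = dict(cfg.get("simulate", {}))
    taxonomy = default_taxonomy()
    marker = sim_cfg.pop("marker", "vacuole")
    n_strains = int(sim_cfg.pop("n_strains", 30))
    gcfg = simulate.GeneratorConfig(seed=seed, marker=marker, taxonomy=taxonomy, **sim_cfg)
    gcfg.strains = simulate.random_strains(
        n_strains, seed, taxonomy.classes_of(marker), gcfg.wild_type_class
    )
    table, layouts, truth = _stage("simulate")(simulate.generate_screen)(gcfg)
    write_feature_table(table, outdir / "cells_raw.tsv")
    truth.strain_truth.to_csv(outdir / "ground_truth_strains.tsv", sep="\t", index=False)
    truth.cell_truth.to_csv(outdir / "ground_truth_cells.tsv", sep="\t", index=False)
    paths["cells_raw"] = outdir / "cells_raw.tsv"

    # --- qc + standardize -------------------------------------------------
    qcfg = qc.QcConfig(**cfg.get("qc", {}))
    table, plate_stats = _stage("standardize")(qc.standardize_per_plate)(table, layouts)
    table = _stage("qc")(qc.apply_hard_filters)(table, qcfg)
    qc.qc_report(table).to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
    paths["qc_report"] = outdir / "qc_report.tsv"

    # --- outlier detection ------------------------------------------------
    ocfg = outliers.OutlierDetectorConfig(seed=seed, **cfg.get("outliers", {}))
    good = table.good_cells()
    proj = _stage("detect-outliers")(outliers.fit_pca)(table, ocfg)
    control_wells = {p: layouts[p].control_wells for p in layouts}
    is_control = [
        w in control_wells[p] for p, w in zip(good["plate_id"], good["well_id"])
    ]
    ctrl_X = good.loc[is_control, list(table.schema.feature_names)].to_numpy(float)
    model = outliers.fit_outlier_detector(ctrl_X, ocfg, projection=proj)
    flags = outliers.detect_outliers(table, model)
    strain_table = outliers.strain_outlier_table(
        flags, good["strain_id"], wt_strain_id=gcfg.control_strain
    )
    strain_table.to_csv(outdir / "unsupervised_penetrance.tsv", sep="\t", index=False)
    paths["unsupervised_penetrance"] = outdir / "unsupervised_penetrance.tsv"

    # --- train + classify -------------------------------------------------
    ccfg = classify.ClassifierConfig(seed=seed, **cfg.get("classifier", {}))
    n_per_class = int(cfg.get("training", {}).get("n_per_class", 60))
    ts, _ = simulate.generate_training_set(gcfg, n_per_class)
    ensemble = _stage("train")(classify.train_final)(ts, ccfg)
    ensemble.save(outdir / "model")
    preds = _stage("classify")(classify.classify_cells)(table, ensemble)
    preds.to_csv(outdir / "predictions.tsv", sep="\t", index=False, float_format="%.6g")
    paths["predictions"] = outdir / "predictions.tsv"

    # --- strain summaries + calling ---------------------------------------
    call_cfg = calls.CallConfig(**cfg.get("calls", {}))
    call_table, pen_thr = call_mutants_from_predictions(
        preds, good, taxonomy, marker,
        control_strain=gcfg.control_strain,
        condition=gcfg.condition,
        screen_type=gcfg.screen_type,
        call_cfg=call_cfg,
    )
    call_table.to_csv(outdir / "mutant_calls.tsv", sep="\t", index=False, float_format="%.6g")
    paths["mutant_calls"] = outdir / "mutant_calls.tsv"
    consensus = calls.consensus_gene_calls(call_table, call_cfg)
    consensus.to_csv(outdir / "consensus_calls.tsv", sep="\t", index=False, float_format="%.6g")
    paths["consensus_calls"] = outdir / "consensus_calls.tsv"

    # --- report ------------------------------------------------------------
    report = {
        "seed": seed,
        "marker": marker,
        "n_strains": n_strains,
        "n_cells": len(table),
        "n_good_cells": int(table.good_mask.sum()),
        "n_pcs": model.n_pcs,
        "penetrance_threshold": pen_thr.value,
        "n_penetrance_mutants": int(call_table["is_penetrance_mutant"].sum()) if len(call_table) else 0,
        "n_spms": int(call_table["is_spm"].sum()) if len(call_table) else 0,
        "outputs": {k: str(v) for k, v in paths.items()},
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    paths["report"] = outdir / "report.json"
    return paths
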