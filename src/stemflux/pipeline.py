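"""End-to-end orchestration: simulate -> qc -> partition -> evaluate.

``run_pipeline`` binds the stages into a reproducible run: it writes every
tabular artifact as CSV plus a JSON manifest carrying the config hash, the
seeds, and per-stage row counts, so a run is regenerable from the manifest
alone and two runs with the same config and seed produce byte-identical
numeric artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import io as sio
from .config import ArtifactConfig, PipelineConfig, SimConfig
from .evaluate import (monthly_contributions, diurnal_means, recovery_report,
                       train_test_split, validate_reconstruction)
from .partition import fit_season, partition_series
from .qc import (align, filter_high_rh, filter_outliers_3sd, flag_counts,
                 select_low_sapflow, technical_qc)
from .synthetic import SimTruth, default_truth, generate_drivers, generate_true_fluxes, inject_artifacts


def _config_hash(*configs) -> str:
    blob = json.dumps([asdict(c) for c in configs], sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(
    outdir,
    sim: SimConfig | None = None,
    truth: SimTruth | None = None,
    artifacts: ArtifactConfig | None = None,
    pipeline: PipelineConfig | None = None,
    tech_limits: dict | None = None,
) -> dict:
    """Execute the full synthetic-data partitioning pipeline.

    Stages: simulate drivers and chamber fluxes (with optional planted QC
    artifacts), flag-and-drop QC, align, monthly parameter fits, component
    series, 8:2 holdout validation, diurnal means, contribution fractions and
    (synthetic runs) parameter recovery.  Writes CSV/JSON artifacts under
    ``outdir`` and returns a result dict with the in-memory tables and the
    manifest.
    """
    sim = sim or SimConfig()
    truth = truth or default_truth()
    pipeline = pipeline or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    # --- simulate ---------------------------------------------------------
    drivers = generate_drivers(sim)
    dark, transparent, truth_components = generate_true_fluxes(drivers, truth)
    artifact_log = pd.DataFrame(columns=["kind", "timestamp", "chamber"])
    if artifacts is not None:
        dark, transparent, drivers, artifact_log = inject_artifacts(
            dark, transparent, drivers, artifacts)
    counts["drivers"] = len(drivers)
    counts["dark_in"] = len(dark)
    counts["transparent_in"] = len(transparent)

    # --- qc ---------------------------------------------------------------
    tech_limits = tech_limits or {}
    dark = technical_qc(dark, tech_limits)
    transparent = technical_qc(transparent, tech_limits)
    dark = filter_outliers_3sd(dark, sd_mult=pipeline.sd_mult)
    transparent = filter_outliers_3sd(transparent, sd_mult=pipeline.sd_mult)
    dark = filter_high_rh(dark, drivers, pipeline.rh_threshold_pct)
    transparent = filter_high_rh(transparent, drivers, pipeline.rh_threshold_pct)
    table, align_report = align(dark, transparent, drivers)
    low_flow, low_n = select_low_sapflow(
        table, threshold=pipeline.sapflow_threshold, mode=pipeline.sapflow_mode,
        fraction=pipeline.sapflow_fraction)
    counts["aligned"] = len(table)
    counts["low_sapflow"] = len(low_flow)

    # --- partition --------------------------------------------------------
    fits = fit_season(table, low_flow, min_n=pipeline.min_n,
                      ppfd_day_threshold=pipeline.ppfd_day_threshold)
    components = partition_series(table, fits, pipeline.ppfd_day_threshold)
    counts["components"] = len(components)

    # --- evaluate ---------------------------------------------------------
    train, test = train_test_split(
        table, ratio=pipeline.split_ratio, seed=pipeline.split_seed,
        stratify_by_month=pipeline.stratify_split_by_month)
    train_low, _ = select_low_sapflow(
        train, threshold=pipeline.sapflow_threshold, mode=pipeline.sapflow_mode,
        fraction=pipeline.sapflow_fraction)
    fits_train = fit_season(train, train_low, min_n=pipeline.min_n,
                            ppfd_day_threshold=pipeline.ppfd_day_threshold)
    validation = validate_reconstruction(test, fits_train,
                                         pipeline.ppfd_day_threshold)
    diurnal = diurnal_means(components)
    contributions = monthly_contributions(components,
                                          per_row=pipeline.contribution_per_row)
    recovery = recovery_report(fits, truth)
    counts["train"] = len(train)
    counts["test"] = len(test)

    # --- artifacts --------------------------------------------------------
    sio.write_timeseries(drivers, outdir / "drivers.csv")
    sio.write_timeseries(dark, outdir / "flux_dark.csv")
    sio.write_timeseries(transparent, outdir / "flux_transparent.csv")
    sio.write_timeseries(truth_components, outdir / "truth.csv")
    sio.write_timeseries(components, outdir / "components.csv")
    fits.to_frame().to_csv(outdir / "params.csv", index=False)
    validation.to_csv(outdir / "validation.csv", index=False)
    diurnal.to_csv(outdir / "diurnal_means.csv", index=False)
    contributions.to_csv(outdir / "contributions.csv", index=False)
    recovery.to_csv(outdir / "recovery.csv", index=False)
    if len(artifact_log):
        artifact_log.to_csv(outdir / "artifact_log.csv", index=False)
    sio.write_json({
        "r0": truth.r0, "b": truth.b, "pmax": truth.pmax, "f": truth.f,
        "e": truth.e, "noise_sd": truth.noise_sd, "rng_seed": truth.rng_seed,
    }, outdir / "truth_params.json")

    qc_report = {
        "align": align_report,
        "low_sapflow_per_month": low_n,
        "dark_flags": flag_counts(dark),
        "transparent_flags": flag_counts(transparent),
        "planted_artifacts": int(len(artifact_log)),
    }
    sio.write_json(qc_report, outdir / "qc_report.json")

    manifest = {
        "config_hash": _config_hash(sim, pipeline),
        "sim": asdict(sim),
        "pipeline": pipeline.to_dict(),
        "truth_seed": truth.rng_seed,
        "noise_sd": truth.noise_sd,
        "row_counts": counts,
    }
    sio.write_json(manifest, outdir / "manifest.json")

    return {
        "drivers": drivers, "dark": dark, "transparent": transparent,
        "table": table, "low_flow": low_flow, "fits": fits,
        "fits_train": fits_train, "components": components,
        "validation": validation, "diurnal": diurnal,
        "contributions": contributions, "recovery": recovery,
        "qc_report": qc_report, "manifest": manifest,
        "truth_components": truth_components, "artifact_log": artifact_log,
    }
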