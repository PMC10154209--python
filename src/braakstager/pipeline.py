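"""End-to-end orchestration: calibrate -> stage -> transitions -> trajectories.

`run_pipeline` executes the whole analysis on either simulated or user
tables, writes every output as CSV plus a machine-readable run record
(resolved config, seed, package version, input checksums) and returns the
in-memory results.  All randomness flows from the config seed through named
substreams, so a rerun with the same config is numerically identical.
"""

from __future__ import annotations

import hashlib
import zlib
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import dump_config
from .io import read_cohort_table, write_cohort_table
from .longitudinal import (
    INTERVALS,
    amyloid_gated_progression,
    gating_report,
    paths_from_assignments,
    summarize_transitions,
)
from .staging import calibrate_cutoffs, stage_table
from .synthetic import GeneratorConfig, generate_calibration_sample, generate_cross_section, \
    generate_longitudinal, pipeline_view
from .trajectories import (
    analyze_trajectory,
    build_domain_composites,
    cdr_stage_table,
    default_direction,
)
from .stats import compare_positivity_proportions, compute_eyo, eyo_stage_association


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _stats_rng(seed: int, channel: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(channel.encode())])
    )


def simulate_tables(cfg: dict):
    """Generate (calibration, cohort-with-truth) tables from the config."""
    gen_cfg = GeneratorConfig(seed=int(cfg["seed"]), **cfg.get("generator", {}))
    calibration = generate_calibration_sample(gen_cfg)
    baseline = generate_cross_section(gen_cfg)
    followups = generate_longitudinal(gen_cfg, baseline)
    cohort = pd.concat([baseline, followups], ignore_index=True)
    return calibration, cohort


def run_pipeline(
    cfg: dict,
    out_dir,
    input_table: Optional[str] = None,
    calibration_table: Optional[str] = None,
) -> Dict[str, object]:
    """Run the full analysis and write all outputs under ``out_dir``.

    Without ``input_table``/``calibration_table`` paths a synthetic cohort is
    generated from the config.  Fails fast if a referenced table is missing.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    checksums: Dict[str, str] = {}

    if input_table is None:
        calibration, cohort = simulate_tables(cfg)
        write_cohort_table(calibration, out_dir / "calibration.csv")
        write_cohort_table(pipeline_view(cohort), out_dir / "cohort.csv")
        write_cohort_table(cohort, out_dir / "cohort_with_truth.csv")
        checksums["calibration.csv"] = _sha256(out_dir / "calibration.csv")
        checksums["cohort.csv"] = _sha256(out_dir / "cohort.csv")
    else:
        if calibration_table is None:
            raise ValueError("a calibration table is required when an input table is given")
        for p in (input_table, calibration_table):
            if not Path(p).exists():
                raise FileNotFoundError(f"input table not found: {p}")
        checksums[str(input_table)] = _sha256(Path(input_table))
        checksums[str(calibration_table)] = _sha256(Path(calibration_table))
        cohort = read_cohort_table(input_table)
        calibration = read_cohort_table(
            calibration_table,
            required=[f"suvr_braak{i}" for i in range(1, 7)],
        )

    # -- staging ----------------------------------------------------------
    cutoffs = calibrate_cutoffs(calibration, k_sd=float(cfg["k_sd"]))
    assignments = stage_table(
        cohort,
        cutoffs,
        meta_roi_threshold=cfg.get("meta_roi_threshold"),
        pet_threshold=float(cfg["pet_threshold"]),
        csf_ratio_threshold=float(cfg["csf_ratio_threshold"]),
    )
    write_cohort_table(assignments, out_dir / "assignments.csv")

    results: Dict[str, object] = {
        "cutoffs": cutoffs,
        "assignments": assignments,
        "transitions": {},
        "trajectories": {},
    }

    # -- longitudinal transitions -----------------------------------------
    try:
        paths = paths_from_assignments(assignments)
    except ValueError:
        paths = []
    gating = None
    if paths:
        for interval in INTERVALS:
            if not any(p.interval == interval for p in paths):
                continue
            summary = summarize_transitions(paths, interval)
            results["transitions"][interval] = summary
            pd.DataFrame(
                summary.counts,
                index=pd.Index(range(7), name="baseline_stage"),
                columns=[f"followup_{s}" for s in range(7)],
            ).to_csv(out_dir / f"transition_matrix_{interval}.csv")
        if all(p.baseline_amyloid_positive is not None for p in paths):
            progression = amyloid_gated_progression(paths)
            progression.to_csv(out_dir / "amyloid_gated_progression.csv")
            gating = gating_report(progression, gate_stage=int(cfg["gate_stage"]))
            results["gating"] = gating

    # -- stage-indexed trajectories (baseline visits only) ----------------
    baseline = cohort[cohort["visit"] == "baseline"].reset_index(drop=True)
    base_assign = assignments[assignments["visit"] == "baseline"].reset_index(drop=True)
    stages = base_assign["stage"].to_numpy()
    reference_mask = (baseline["diagnosis"] == "CU").to_numpy()
    work = baseline.copy()
    if {"csf_ab42", "csf_ab40"}.issubset(work.columns):
        work["csf_ab42_ab40_ratio"] = work["csf_ab42"] / work["csf_ab40"]
    composites = None
    if any(c in work.columns for c in ("logical_memory_immediate", "ravlt_immediate")):
        composites = build_domain_composites(work, reference_mask)
        for c in composites.columns:
            work[c] = composites[c]

    biomarkers = [b for b in cfg["trajectory_biomarkers"] if b in work.columns]
    if composites is not None:
        biomarkers += [c for c in composites.columns if c not in biomarkers]
    lower_is_abnormal = set(cfg.get("orientation_lower_is_abnormal") or [])
    curves = {}
    contrast_rows = []
    for biomarker in biomarkers:
        direction = (
            "lower"
            if biomarker in lower_is_abnormal
            else default_direction(biomarker)
        )
        try:
            result = analyze_trajectory(
                work[biomarker].to_numpy(dtype=float),
                stages,
                reference_mask,
                biomarker=biomarker,
                direction=direction,
                span=float(cfg["loess_span"]),
                n_mc=int(cfg["dunnett_draws"]),
                rng=_stats_rng(int(cfg["seed"]), f"dunnett/{biomarker}"),
            )
        except ValueError:
            continue  # biomarker absent/constant in this cohort
        results["trajectories"][biomarker] = result
        result.to_frame().to_csv(out_dir / f"trajectory_{biomarker}.csv", index=False)
        curves[biomarker] = result.scaled_curve
        for stage, row in result.comparison.contrasts.iterrows():
            contrast_rows.append(
                {
                    "biomarker": biomarker,
                    "stage": stage,
                    "estimate": row["estimate"],
                    "p_unadjusted": row["p_unadjusted"],
                    "p_adjusted": row["p_adjusted"],
                    "omnibus_F": result.comparison.omnibus.statistic,
                    "omnibus_p": result.comparison.omnibus.pvalue,
                }
            )
    if contrast_rows:
        pd.DataFrame(contrast_rows).to_csv(out_dir / "stage_contrasts.csv", index=False)
    if curves:
        scaled = pd.DataFrame(curves, index=pd.Index(range(7), name="stage"))
        scaled.to_csv(out_dir / "scaled_curves.csv")
        _plot_scaled_curves(scaled, out_dir / "scaled_curves.png")

    # -- CDR-by-stage summary and amyloid positivity proportions ----------
    if "cdr" in work.columns:
        cdr_table = cdr_stage_table(work["cdr"].to_numpy(), stages)
        cdr_table.to_csv(out_dir / "cdr_by_stage.csv")
        results["cdr_by_stage"] = cdr_table
    amyloid_flags = base_assign["amyloid_pet_positive"]
    if amyloid_flags.notna().any():
        rows = []
        for a, b in cfg.get("proportion_stage_pairs", []):
            try:
                rows.append(
                    compare_positivity_proportions(
                        amyloid_flags.to_numpy(), stages, [(int(a), int(b))]
                    )
                )
            except ValueError:
                continue  # a margin is empty for this pair in this cohort
        if rows:
            proportions = pd.concat(rows, ignore_index=True)
            proportions.to_csv(out_dir / "amyloid_proportion_tests.csv", index=False)
            results["amyloid_proportions"] = proportions

    # -- years-to-onset (autosomal-dominant subsample) --------------------
    if {"psen1_carrier", "parental_onset_age"}.issubset(cohort.columns):
        carriers = (
            cohort["psen1_carrier"].map(lambda v: bool(v) if pd.notna(v) else False).to_numpy()
        )
        if carriers.sum() >= 3:
            merged = cohort.loc[carriers, ["subject_id", "visit", "age_years", "parental_onset_age"]]
            merged = merged.merge(assignments[["subject_id", "visit", "stage"]],
                                  on=["subject_id", "visit"])
            eyo = compute_eyo(
                merged["age_years"].to_numpy(), merged["parental_onset_age"].to_numpy()
            )
            try:
                rho, p = eyo_stage_association(
                    eyo,
                    merged["stage"].to_numpy(),
                    n_permutations=int(cfg["n_permutations"]),
                    rng=_stats_rng(int(cfg["seed"]), "eyo"),
                )
                results["eyo"] = {"rho": rho, "pvalue": p, "n_scans": int(len(merged))}
            except ValueError:
                pass

    # -- run record -------------------------------------------------------
    record = {
        "package_version": __version__,
        "seed": int(cfg["seed"]),
        "config": cfg,
        "input_checksums": checksums,
        "outputs": sorted(p.name for p in out_dir.iterdir() if p.is_file()),
    }
    dump_config(record, out_dir / "run_record.yaml")
    return results


def _plot_scaled_curves(scaled: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for col in scaled.columns:
        ax.plot(scaled.index, scaled[col], label=col, lw=1.8)
    ax.set_xlabel("PET-based Braak stage")
    ax.set_ylabel("scaled abnormality (0-10)")
    ax.set_ylim(-0.3, 10.3)
    ax.legend(fontsize=6, ncols=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
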