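"""End-to-end orchestration: simulate → read → kinetics → dynamics → stats.

Every stage goes through the same readers and writers a real-data run would
use, so a pipeline run on the synthetic cohort exercises the full surface.
All randomness flows from a single seed; re-running with the same seed and
config reproduces every numeric output byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import community_metrics as cm
from . import io_formats as iof
from . import kinetics, trajectory_stats as ts
from .io_formats import DYNAMICS_STEPS, PipelineConfig
from .synthetic_data import SimConfig, generate_cohort, write_cohort

logger = logging.getLogger(__name__)


def simulate(out_dir: str | Path, seed: int, sim_config: SimConfig | None = None) -> dict:
    """Generate a synthetic cohort and write its raw file set."""
    cfg = sim_config or SimConfig()
    cfg.seed = seed
    cohort = generate_cohort(cfg)
    paths = write_cohort(cohort, out_dir)
    logger.info("wrote synthetic cohort (%d lineages) to %s",
                cfg.n_lineages, out_dir)
    return paths


def load_lineages(raw_dir: str | Path, config: PipelineConfig) -> list[iof.Lineage]:
    """Read the raw file set back into assembled lineages."""
    raw = Path(raw_dir)
    meta = iof.read_metadata(raw / "metadata.tsv")
    profiles = iof.read_abundance(raw / "abundance.tsv", raw / "taxonomy.tsv")
    mapping = {
        str(r.sample_id): (str(r.lineage_id), str(r.step))
        for r in meta.itertuples()
        if r.step != "T0"
    }
    curves = []
    for path in sorted((raw / "ph_logs").glob("*.csv")):
        curves.extend(iof.read_ph_log(path, mapping))
    return iof.assemble_lineages(profiles, curves, meta, config)


def extract_kinetics_table(lineages: list[iof.Lineage], config: PipelineConfig) -> pd.DataFrame:
    """Acidification parameters for every curve in the cohort."""
    rows = []
    for lin in lineages:
        for rec in lin.ordered_steps():
            if rec.curve is None:
                continue
            p = kinetics.extract_params(rec.curve, config, horizon_h=rec.horizon_h)
            rows.append({
                "lineage_id": p.lineage_id,
                "step": p.step,
                "lag_h": p.lag_h,
                "mar": p.mar,
                "abs_mar": abs(p.mar),
                "final_ph": p.final_ph,
                "mar_window_start_index": p.mar_window_start_index,
                "eligible": p.eligible,
                "flags": ";".join(p.flags),
            })
    return pd.DataFrame(rows)


def run_all(
    out_dir: str | Path,
    seed: int = 0,
    sim_config: SimConfig | None = None,
    config: PipelineConfig | None = None,
) -> dict:
    """Full analysis on a freshly simulated cohort; returns key results.

    Writes under ``out_dir``: the raw synthetic file set (``raw/``),
    acidification_params.tsv, dynamics_summary.tsv, dynamics_pairs.tsv,
    genus_composition.tsv, nmds_coords.tsv, trajectories.tsv,
    stability_labels.tsv, breakpoint_fit.json, summary_stats.json and
    run_metadata.json.
    """
    out = Path(out_dir)
    config = config or PipelineConfig(rng_seed=seed)
    simulate(out / "raw", seed, sim_config)
    lineages = load_lineages(out / "raw", config)

    params = extract_kinetics_table(lineages, config)
    params_by_lin: dict[str, dict[str, kinetics.AcidificationParams]] = {}
    for lin in lineages:
        d = {}
        for rec in lin.ordered_steps():
            if rec.curve is not None:
                d[rec.step] = kinetics.extract_params(rec.curve, config, horizon_h=rec.horizon_h)
        params_by_lin[lin.lineage_id] = d

    # per-lineage dynamics summaries
    summaries = {
        lin.lineage_id: cm.build_dynamics_summary(
            lin, config, params_by_lin[lin.lineage_id]
        )
        for lin in lineages
    }
    labels = {lid: ts.classify_stability(s, config) for lid, s in summaries.items()}

    pair_rows, summary_rows, genus_tables = [], [], []
    for lin in lineages:
        s = summaries[lin.lineage_id]
        dph = dict(s.delta_final_ph)
        for pair, bc in s.bc_adjacent:
            pair_rows.append({
                "lineage_id": lin.lineage_id,
                "step_pair": pair,
                "bray_curtis": bc,
                "d_final_ph": dph.get(pair, float("nan")),
            })
        lab = labels[lin.lineage_id]
        summary_rows.append({
            "lineage_id": lin.lineage_id,
            "bc_sum": s.bc_sum,
            "mean_adjacent_bc": float(np.mean([v for _, v in s.bc_adjacent]))
            if s.bc_adjacent else float("nan"),
            "shannon_fluct_sum": s.shannon_fluct_sum,
            "richness_fluct_sum": s.richness_fluct_sum,
            "richness_f6": s.richness_series.get("F6", np.nan),
            "shannon_f6": s.shannon_series.get("F6", np.nan),
            "lab_fraction_f6": s.lab_fraction_series.get("F6", np.nan),
            "dominant_f2": s.dominant_taxon_series.get("F2", ""),
            "dominant_f6": s.dominant_taxon_series.get("F6", ""),
            "stability_label": lab.label,
            "bc_trend_r": lab.evidence.get("bc_trend_r", float("nan")),
        })
        gt = cm.aggregate_minor_genera(lin, config.minor_genus_threshold,
                                       config.lactobacillus_aliases)
        gt = gt.reset_index().assign(lineage_id=lin.lineage_id)
        genus_tables.append(gt)

    pairs_df = pd.DataFrame(pair_rows)
    summary_df = pd.DataFrame(summary_rows)
    genus_df = pd.concat(genus_tables, ignore_index=True) if genus_tables else pd.DataFrame()

    # structure-function correlation over pooled pairs
    r_sf, p_sf, n_sf = ts.correlate_structure_function(
        pairs_df["bray_curtis"], pairs_df["d_final_ph"], use_abs=True
    )

    # NMDS over all F2..F6 profiles
    dyn_profiles = [
        lin.profile_at(s) for lin in lineages for s in DYNAMICS_STEPS
        if lin.profile_at(s) is not None
    ]
    bc_matrix = cm.bray_curtis_matrix(dyn_profiles)
    ordination = ts.nmds(
        bc_matrix, k=config.nmds_dimensions,
        seed=config.rng_seed, n_restarts=config.nmds_restarts,
    )
    coords_df = ordination.coords.reset_index(names="sample_id")
    coords_df["stress"] = ordination.stress

    traj_rows = []
    trajectories = []
    for lin in lineages:
        order = [f"{lin.lineage_id}_{s}" for s in DYNAMICS_STEPS
                 if lin.profile_at(s) is not None]
        if len(order) < 2:
            continue
        t = ts.lineage_trajectory(ordination, order, lin.lineage_id)
        trajectories.append(t)
        traj_rows.append({
            "lineage_id": t.lineage_id,
            "total_length": t.total_length,
            "net_displacement": t.net_displacement,
            "direction_angle": t.direction_angle,
        })
    traj_df = pd.DataFrame(traj_rows)

    labels_df = pd.DataFrame([
        {"lineage_id": lid, "label": lab.label, **lab.evidence}
        for lid, lab in labels.items()
    ])

    # breakpoint regression of lag time on LAB percentage, pooled F2..F6
    lab_pct, lags = [], []
    for lin in lineages:
        for step in DYNAMICS_STEPS:
            prof = lin.profile_at(step)
            p = params_by_lin[lin.lineage_id].get(step)
            if prof is None or p is None or not p.eligible or not np.isfinite(p.lag_h):
                continue
            lab_pct.append(cm.lab_fraction(prof, config.lab_genera,
                                           config.lactobacillus_aliases) * 100.0)
            lags.append(p.lag_h)
    bp = ts.breakpoint_regression(lab_pct, lags, grid_step=config.breakpoint_grid_step * 100.0)

    summary_stats = {
        "structure_function": {"r": r_sf, "p": p_sf, "n": n_sf},
        "nmds_stress": ordination.stress,
        "breakpoint": {
            "lab_percent": bp.breakpoint,
            "slope_left": bp.slope_left,
            "slope_right": bp.slope_right,
            "p_left": bp.p_left,
            "p_right": bp.p_right,
            "flags": list(bp.flags),
        },
        "n_lineages": len(lineages),
        "n_curves": int(len(params)),
    }

    iof.write_results(
        {
            "acidification_params": params,
            "dynamics_summary": summary_df,
            "dynamics_pairs": pairs_df,
            "genus_composition": genus_df,
            "nmds_coords": coords_df,
            "trajectories": traj_df,
            "stability_labels": labels_df,
        },
        out, config=config, seed=seed,
    )
    with open(out / "breakpoint_fit.json", "w") as fh:
        json.dump(summary_stats["breakpoint"], fh, indent=2, sort_keys=True)
    with open(out / "summary_stats.json", "w") as fh:
        json.dump(summary_stats, fh, indent=2, sort_keys=True)
    return {
        "params": params,
        "summaries": summaries,
        "labels": labels,
        "pairs": pairs_df,
        "ordination": ordination,
        "trajectories": trajectories,
        "breakpoint": bp,
        "summary_stats": summary_stats,
    }
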