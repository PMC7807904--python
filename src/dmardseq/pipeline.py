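"""End-to-end pipeline: simulate -> states -> Markov -> mining -> models -> report.

Each stage reads and writes plain CSV/JSON artifacts so intermediate results
are diff-able, and a manifest records the seed, parameters and row counts at
every stage boundary (the declining-denominator audit the occupancy table
implies).  The run is idempotent given the same inputs and seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .grids import GridPolicy, build_state_grids, carry_forward_covariates
from .markov import occupancy, transition_counts
from .mining import (
    bdmard_preceded_share,
    episodes_from_grids,
    mine_target_trajectories,
    prior_state_distribution,
    time_to_target,
)
from .models import ModelSpec, build_panel, fit_logistic, fit_longitudinal, stratified_fit, univariable_screen
from .reporting import cohort_table, render_trajectory_plot
from .simulate import SimConfig, generate_registry
from .states import TreatmentState

BASELINE_CANDIDATES = [
    "age_c",
    "male",
    "duration_c",
    "serostatus",
    "csdmard_baseline",
    "glucocorticoid_baseline",
    "cdai_cat",
    "comorbidity_count",
]
LONGITUDINAL_CANDIDATES = BASELINE_CANDIDATES + [
    "state",
    "ever_tcz_combo",
    "ever_tnfi",
    "ever_other_bdmard",
]


def config_from_yaml(path: str | Path) -> SimConfig:
    """Load a simulation config from YAML (unknown keys rejected)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    fields = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(raw) - fields
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "target_state" in raw:
        raw["target_state"] = TreatmentState(raw["target_state"])
    if "kernel" in raw:
        raw["kernel"] = np.asarray(raw["kernel"], float)
    if "visit_gap_months" in raw:
        raw["visit_gap_months"] = tuple(raw["visit_gap_months"])
    return SimConfig(**raw)


def _baseline_table(
    patients: pd.DataFrame,
    grids: pd.DataFrame,
    target: TreatmentState | set[TreatmentState],
) -> pd.DataFrame:
    """Patient-level table with baseline features and the ever-target outcome.

    ``target`` may be a single state or a set (e.g. both TCZ states for the
    any-TCZ outcome).
    """
    from .models import cdai_category
    from .simulate import AGE_CENTER, DURATION_CENTER, COMORBIDITY_COLUMNS

    targets = {target} if isinstance(target, TreatmentState) else set(target)
    names = {t.value for t in targets}
    reachers = set(grids.loc[grids["state"].isin(names), "patient_id"].unique())
    tab = patients[patients["patient_id"].isin(grids["patient_id"].unique())].copy()
    tab["outcome"] = tab["patient_id"].isin(reachers).astype(int)
    tab["age_c"] = tab["age_years"] - AGE_CENTER
    tab["duration_c"] = tab["disease_duration_years"] - DURATION_CENTER
    tab["male"] = (tab["sex"] == "male").astype(int)
    tab["cdai_cat"] = cdai_category(tab["cdai_baseline"])
    como = [c for c in COMORBIDITY_COLUMNS if c in tab.columns]
    tab["comorbidity_count"] = tab[como].sum(axis=1)
    return tab


def run_pipeline(
    config: SimConfig,
    out_dir: str | Path,
    policy: GridPolicy = GridPolicy(),
    lookback: int = 4,
    min_count: int = 4,
    fit_models: bool = True,
) -> dict:
    """Execute the full analysis and write artifacts + manifest to ``out_dir``.

    Returns the manifest dict.  Artifacts: patients.csv, visits.csv,
    state_grids.csv, occupancy.csv, transitions_pooled.csv, trajectories.csv,
    summary.json, cohort_table.csv, model_*.csv, trajectories.svg/.png,
    manifest.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "n_patients": config.n_patients,
        "target_state": config.target_state.value,
        "policy": {"window": policy.window_halfwidth_months, "gap_rule": policy.gap_rule},
        "lookback": lookback,
        "min_count": min_count,
        "stages": {},
    }

    patients, visits = generate_registry(config)
    patients.to_csv(out / "patients.csv", index=False)
    visits.to_csv(out / "visits.csv", index=False)
    manifest["stages"]["simulate"] = {"patients": len(patients), "visits": len(visits)}

    visits_cf = carry_forward_covariates(visits)
    grids = build_state_grids(visits_cf, policy=policy, horizon_months=config.horizon_months)
    grids.to_csv(out / "state_grids.csv", index=False)
    manifest["stages"]["build"] = {
        "patients_in_cohort": int(grids["patient_id"].nunique()),
        "grid_cells": len(grids),
    }

    occ = occupancy(grids)
    occ.formatted().to_csv(out / "occupancy.csv")
    pooled = transition_counts(grids, pooled=True)
    pooled.probabilities.to_csv(out / "transitions_pooled.csv")
    per_interval = transition_counts(grids, pooled=False)
    for tbl in per_interval:
        tbl.probabilities.to_csv(out / f"transitions_{tbl.interval:02d}.csv")
    manifest["stages"]["markov"] = {
        "n_pairs": pooled.n_pairs,
        "n_at_risk": {str(k): int(v) for k, v in occ.n_at_risk.items()},
    }

    episodes = episodes_from_grids(grids)
    catalog = mine_target_trajectories(episodes, config.target_state, lookback, min_count)
    catalog.to_frame().to_csv(out / "trajectories.csv", index=False)
    ttt = time_to_target(grids, config.target_state)
    shares = prior_state_distribution(episodes, config.target_state)
    summary = {
        "target": config.target_state.value,
        "n_reachers": ttt.n_reachers,
        "n_never": ttt.n_never,
        "median_months": ttt.median_months,
        "iqr_months": ttt.iqr_months,
        "fraction_within_36": ttt.fraction_within_36,
        "median_prior_bdmards": ttt.median_prior_bdmards,
        "range_prior_bdmards": ttt.range_prior_bdmards,
        "prior_state_shares": shares,
        "bdmard_preceded_share": bdmard_preceded_share(shares, config.target_state),
        "quantile_method": "midpoint",
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    manifest["stages"]["mine"] = {"n_reachers": ttt.n_reachers, "n_sequences": len(catalog.sequences)}

    cohort = cohort_table(patients, grids, config.target_state)
    cohort.to_csv(out / "cohort_table.csv")
    for ext in ("svg", "png"):
        render_trajectory_plot(catalog, str(out / f"trajectories.{ext}"))

    if fit_models and ttt.n_reachers > 0:
        baseline = _baseline_table(patients, grids, config.target_state)
        selected = univariable_screen(baseline, "outcome", BASELINE_CANDIDATES)
        fit_base = fit_logistic(baseline, "outcome", selected)
        fit_base.table.assign(dropped=False).to_csv(out / "model_baseline.csv", index=False)

        panel = build_panel(grids, patients, ModelSpec(outcome="tcz_mono", time_updated=True))
        selected_l = univariable_screen(panel, "outcome", LONGITUDINAL_CANDIDATES)
        fit_long = fit_longitudinal(panel, "outcome", selected_l)
        fit_long.table.to_csv(out / "model_longitudinal.csv", index=False)
        strata = stratified_fit(panel, "outcome", selected_l)
        for name, fit in strata.items():
            if fit is not None:
                fit.table.to_csv(out / f"model_{name.replace('=', '_')}.csv", index=False)
        manifest["stages"]["model"] = {
            "baseline_selected": selected,
            "longitudinal_selected": selected_l,
            "baseline_n": fit_base.n_obs,
            "panel_rows": len(panel),
            "panel_clusters": fit_long.n_clusters,
            "dropped_for_separation": fit_long.dropped,
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
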