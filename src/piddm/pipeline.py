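"""End-to-end analysis pipeline: synthesize -> filter -> fit -> select -> report.

``run_pipeline`` drives the whole analysis from a single configuration
(a dict, or a YAML/JSON file path) and writes every intermediate artifact
plus a manifest with the seeds and sizes used, so a run can be reproduced
exactly from its output directory.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fitting import FitOptions, apply_rt_cutoffs, fit_cohort, save_fits
from .models import get_model
from .params import CONDITIONS
from .qpp import (
    average_summaries,
    observed_quantiles,
    predicted_summary_for_participant,
    qpp_figure,
)
from .selection import ranking_table, winners_by_participant
from .simulate import SimOptions
from .stats import independent_t, mixed_anova, planned_pi_contrast, summarize_behavior
from .task import (
    CohortSpec,
    GroupSpec,
    SessionDesign,
    group_spec_from_estimates,
    sample_cohort,
    synthesize_dataset,
    write_behavior_csv,
)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "groups": [
        {"label": "young", "n_participants": 25},
        {"label": "older", "n_participants": 38},
    ],
    "design": {},
    "models": [1, 2, 3, 4, 5, 6],
    "fit": {"n_restarts": 5},
    "sim": {"dt": 1e-4, "max_t": 10.0},
}


def load_config(config) -> dict:
    """Accept a dict, or a path to a YAML/JSON config file."""
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    merged = {**DEFAULT_CONFIG, **(config or {})}
    return merged


def _cohort_spec(cfg: Mapping) -> CohortSpec:
    groups = []
    for g in cfg["groups"]:
        if "means" in g:
            groups.append(GroupSpec(g["label"], g["n_participants"], g["means"], g.get("sds", {})))
        else:
            groups.append(
                group_spec_from_estimates(
                    g["label"],
                    n_participants=g.get("n_participants"),
                    sd_from_se=g.get("sd_from_se", True),
                )
            )
    return CohortSpec(groups=groups, seed=int(cfg["seed"]))


def run_pipeline(config, out_dir) -> dict:
    """Run the full analysis and write its artifacts to ``out_dir``.

    Stages: cohort sampling, dataset synthesis, RT cutoffs, per-participant
    model fits, BIC selection, group statistics on behavior and on the
    cohort-winning model's parameters, and the quantile-probability figure.
    Returns the manifest (also written as ``manifest.json``).
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    # --- synthesize ------------------------------------------------------
    design = SessionDesign(**cfg.get("design", {}))
    cohort = sample_cohort(_cohort_spec(cfg))
    sim_cfg = cfg.get("sim", {})
    data = synthesize_dataset(
        cohort,
        design,
        seed=seed,
        sim_options=SimOptions(dt=sim_cfg.get("dt", 1e-4), max_t=sim_cfg.get("max_t", 10.0)),
    )
    write_behavior_csv(data, out / "data.csv")

    # --- preprocess ------------------------------------------------------
    filtered, excluded = apply_rt_cutoffs(data)

    # --- fit & select ----------------------------------------------------
    fit_cfg = cfg.get("fit", {})
    options = FitOptions(n_restarts=int(fit_cfg.get("n_restarts", 5)), seed=seed)
    fits = fit_cohort(filtered, cfg["models"], options)
    save_fits(fits, out / "fits.json")
    if len(cfg["models"]) == 1:  # nothing to select between
        winners = {f.participant_id: f.model_id for f in fits if f.converged}
    else:
        winners = winners_by_participant(fits)
    ranking = ranking_table(winners)
    ranking.to_csv(out / "ranking.csv", index=False)
    best_model = int(ranking.sort_values("rank").iloc[0]["model"])

    # --- group statistics ------------------------------------------------
    behavior = summarize_behavior(filtered)
    behavior.to_csv(out / "behavior_summary.csv", index=False)
    report: dict = {"excluded_fraction": excluded, "best_model": best_model}
    for dv in ("error_rate_pct", "mean_correct_rt_s"):
        anova = mixed_anova(behavior, dv)
        anova.to_csv(out / f"anova_{dv}.csv", index=False)
        contrasts = planned_pi_contrast(behavior, dv)
        report[f"contrasts_{dv}"] = {k: vars(v) for k, v in contrasts.items()}

    best_fits = [f for f in fits if f.model_id == best_model]
    drift = pd.DataFrame(
        [
            {
                "participant_id": f.participant_id,
                "group": data.loc[data["participant_id"] == f.participant_id, "group"].iloc[0],
                "condition": c,
                "v": f.parameters.v[c],
            }
            for f in best_fits
            for c in CONDITIONS
        ]
    )
    anova_v = mixed_anova(drift, "v")
    anova_v.to_csv(out / "anova_drift.csv", index=False)
    report["contrasts_drift"] = {
        k: vars(v) for k, v in planned_pi_contrast(drift, "v").items()
    }
    scalars = pd.DataFrame(
        [
            {
                "participant_id": f.participant_id,
                "group": drift.loc[drift["participant_id"] == f.participant_id, "group"].iloc[0],
                "a": f.parameters.a[CONDITIONS[0]],
                "ter": f.parameters.ter[CONDITIONS[0]],
            }
            for f in best_fits
        ]
    )
    for param in ("a", "ter"):
        res = independent_t(scalars[param], scalars["group"])
        report[f"ttest_{param}"] = vars(res)

    # --- quantile-probability report -------------------------------------
    obs_by_group, pred_by_group = {}, {}
    coding = get_model(best_model).coding
    for group, gdata in filtered.groupby("group"):
        obs = [
            observed_quantiles(sub) for _, sub in gdata.groupby("participant_id")
        ]
        obs_by_group[group] = average_summaries(obs)
        pred = [
            predicted_summary_for_participant(f.parameters, coding)
            for f in best_fits
            if drift.loc[drift["participant_id"] == f.participant_id, "group"].iloc[0] == group
        ]
        pred_by_group[group] = average_summaries(pred)
    figures = qpp_figure(obs_by_group, pred_by_group, str(out / "qpp"))

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "config": cfg,
        "n_participants": len(cohort),
        "n_trials": int(len(data)),
        "excluded_fraction": excluded,
        "best_model": best_model,
        "artifacts": sorted({p.name for p in out.iterdir()} | {"manifest.json"}),
        "report": _jsonable(report),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
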