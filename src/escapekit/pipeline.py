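"""End-to-end pipeline: generate -> simulate -> extract -> detect -> analyze."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as ekio
from .config import PipelineConfig, stage_seed
from .features import FeatureConfig, summarize_epoch
from .kinematics import KinematicParams, generate_epoch_scenario
from .simulate import DEFAULT_THREATS, EffectSpec, generate_cohort, default_design
from .stats import (
    cell_weights,
    contrast_table,
    estimated_marginal_means,
    fit_factorial_mixed,
)
from .vocalization import grid_search_calibrate, monte_carlo_cv, synth_audio

log = logging.getLogger("escapekit")

__all__ = ["DEFAULT_CONTRASTS", "extract_cohort", "analyze_summaries", "run_pipeline"]

#: editable defaults for the hypothesis-family contrasts: best-guess cell
#: selections per dependent variable (the published analysis does not print
#: explicit weight vectors)
DEFAULT_CONTRASTS = {
    "escape_initiation_time": [
        {
            "label": "tti_long_vs_short_attack",
            "plus": {"tti": "long", "behavior": "attack"},
            "minus": {"tti": "short", "behavior": "attack"},
        },
    ],
    "mean_speed": [
        {
            "label": "fast_vs_slow_threat_attack",
            "plus": {"threat": ["elephant", "bear", "human", "dog"], "behavior": "attack"},
            "minus": {"threat": ["snake", "spider"], "behavior": "attack"},
        },
    ],
    "initiated_escape": [
        {
            "label": "divert_short_vs_long_tti",
            "plus": {"tti": "short", "behavior": "divert"},
            "minus": {"tti": "long", "behavior": "divert"},
        },
    ],
}


def extract_cohort(cohort, feature_config: Optional[FeatureConfig] = None) -> pd.DataFrame:
    """Summarize every epoch of a cohort into one tidy row."""
    cfg = feature_config if feature_config is not None else FeatureConfig()
    rows = []
    for ep in cohort.epochs:
        s = summarize_epoch(ep.recording, ep.log, cfg)
        rows.append(
            {
                "subject": ep.subject_id,
                "threat": ep.spec.threat.name,
                "tti": ep.spec.tti_condition,
                "behavior": ep.spec.behavior,
                **s.to_dict(),
            }
        )
    df = pd.DataFrame(rows)
    df["initiated_escape"] = df["initiated_escape"].astype(float)
    return df


def analyze_summaries(
    summaries: pd.DataFrame,
    contrasts: Optional[dict] = None,
    binary_responses: tuple = ("initiated_escape",),
) -> dict:
    """Fit the factorial mixed model per DV and evaluate its contrast family.

    Returns {dv: ContrastTable}.  The Holm correction is applied within
    each DV's family; `pool_holm` in the report applies it jointly.
    """
    spec = contrasts if contrasts is not None else DEFAULT_CONTRASTS
    out = {}
    for dv, clist in spec.items():
        if dv not in summaries.columns:
            continue
        family = "binary" if dv in binary_responses else "continuous"
        data = summaries.dropna(subset=[dv]).copy()
        if family == "binary":
            data[dv] = data[dv].astype(float)
        if data.empty:
            continue
        fit = fit_factorial_mixed(data, dv, family=family)
        emms = estimated_marginal_means(fit)
        weights = {
            c["label"]: cell_weights(emms.cells, c["plus"], c.get("minus"))
            for c in clist
        }
        out[dv] = contrast_table(emms, weights)
    return out


def run_pipeline(config: PipelineConfig, seed: Optional[int] = None, out_dir="report") -> Path:
    """Run every stage under a fanned-out seed and write a report directory."""
    if seed is None:
        seed = config.seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = {"config_hash": config.content_hash(), "seed": seed, "stages": {}}

    params = KinematicParams(
        shelter_position=config.shelter_position,
        fruit_position=config.fruit_position,
        participant_speed=config.participant_speed,
        plan_time=min(config.tti_map.values()),
    )

    # --- generate ----------------------------------------------------------
    g_seed = stage_seed(seed, "generate")
    rng = np.random.default_rng(g_seed)
    design = default_design()
    scenarios = [
        generate_epoch_scenario(
            DEFAULT_THREATS[name], behavior, tti, rng,
            params=params, tti_map=config.tti_map, seed=g_seed,
        )
        for name, tti, behavior in design
    ]
    ekio.write_scenarios(scenarios, out / "scenarios.json")
    report["stages"]["generate"] = {"seed": g_seed, "n_scenarios": len(scenarios)}
    log.info("generate: %d scenarios", len(scenarios))

    # --- simulate ----------------------------------------------------------
    s_seed = stage_seed(seed, "simulate")
    cohort = generate_cohort(
        config.n_subjects,
        design=design,
        effect_spec=EffectSpec(),
        seed=s_seed,
        epochs_per_cell=config.epochs_per_cell,
        dt=config.dt,
    )
    cohort.subjects.to_csv(out / "subjects.csv", index=False)
    report["stages"]["simulate"] = {
        "seed": s_seed,
        "n_subjects": config.n_subjects,
        "n_epochs": len(cohort.epochs),
        "dt": config.dt,
    }
    log.info("simulate: %d epochs", len(cohort.epochs))

    # --- extract -----------------------------------------------------------
    fcfg = FeatureConfig(
        initiation_radius=config.initiation_radius,
        min_outward=config.min_outward,
        smooth_window=config.smooth_window,
        appear_window=config.appear_window,
        min_epoch_duration=config.min_epoch_duration,
        shelter_position=(0.0, config.shelter_position),
    )
    summaries = extract_cohort(cohort, fcfg)
    summaries.to_csv(out / "summaries.csv", index=False)
    report["stages"]["extract"] = {"n_rows": len(summaries)}

    # --- detect ------------------------------------------------------------
    d_seed = stage_seed(seed, "detect")
    rng_d = np.random.default_rng(d_seed)
    clips, labels = synth_audio(config.n_audio_clips, rng=rng_d)
    thresholds = grid_search_calibrate(clips, labels, max_miss=config.detector_max_miss)
    cv = monte_carlo_cv(
        clips, labels, reps=config.detector_reps,
        max_miss=config.detector_max_miss, rng=rng_d,
    )
    report["stages"]["detect"] = {
        "seed": d_seed,
        "volume_threshold": thresholds.volume_threshold,
        "time_threshold": thresholds.time_threshold,
        "cv_mean_miss": cv.mean_miss_rate,
        "cv_mean_false_alarm": cv.mean_false_alarm_rate,
    }
    log.info("detect: thresholds %s", thresholds)

    # --- analyze -----------------------------------------------------------
    tables = analyze_summaries(summaries)
    for dv, table in tables.items():
        table.to_csv(out / f"contrasts_{dv}.csv")
    report["stages"]["analyze"] = {
        dv: {row["label"]: row["p_holm"] for _, row in t.table.iterrows()}
        for dv, t in tables.items()
    }

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return out
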