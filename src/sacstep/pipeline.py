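"""End-to-end pipeline: plan → simulate → (render/detect) → summarize → report.

Configuration is a plain mapping (or a YAML file with the same keys); all
randomness flows from a single integer seed through deterministically
spawned per-subject substreams, so a given config + seed always produces
byte-identical output tables.

Two modes are supported.  ``simulate`` scores the race outcomes directly
(the simulator's labels are ground truth); ``detect`` additionally renders
each trial into a noisy 60 Hz gaze trace and re-derives labels and RTs
through the full detection pipeline, exercising everything a real
recording would.
"""

from __future__ import annotations

import json
import sys
from copy import deepcopy
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .detect import ClassificationConfig, DetectionConfig, classify_rendered_trial
from .gaze import NoiseModel, _ground_truth_dict, render_trial_trace
from .metrics import (
    race_consistency_report,
    summaries_to_frame,
    summarize_subject,
    vincentize,
)
from .race import (
    BehavioralDataset,
    LatencyModel,
    RaceParameters,
    simulate_subject,
)
from .stats import compare_tsrt_table, covariate_correlation, rt_mixed_anova
from .task import ArrayGeometry, StaircaseState, build_experiment_plan

DEFAULT_CONFIG: dict[str, Any] = {
    "mode": "simulate",                 # or "detect"
    "sessions": 4,
    "trials_per_session": 60,
    "proportions": [0.30, 0.40, 0.30],
    "frame_ms": 1000.0 / 60.0,
    "staircase": {"start_ms": 100.0, "step_ms": 67.0},
    "geometry": {"n_positions": 8, "eccentricity_deg": 9.0,
                 "element_size_deg": 0.7},
    "noise": {"fixation_sd_deg": 0.15, "drift_offset_deg": [0.3, -0.2],
              "blink_rate_per_trial": 0.2, "blink_duration_ms": 150.0},
    # Synthetic groups: STOP latencies chosen so group TSRTs fall near
    # typical healthy-control vs patient values; simulation fixtures.
    "groups": {
        "HC": {"n_subjects": 24,
               "go1": {"kind": "exgaussian", "mu_ms": 250, "sigma_ms": 40, "tau_ms": 70},
               "go2": {"kind": "exgaussian", "mu_ms": 240, "sigma_ms": 40, "tau_ms": 70},
               "stop": {"kind": "constant", "value_ms": 160},
               "p_trigger_failure": 0.0},
        "SZP": {"n_subjects": 21,
                "go1": {"kind": "exgaussian", "mu_ms": 250, "sigma_ms": 40, "tau_ms": 70},
                "go2": {"kind": "exgaussian", "mu_ms": 240, "sigma_ms": 40, "tau_ms": 70},
                "stop": {"kind": "constant", "value_ms": 170},
                "p_trigger_failure": 0.0},
    },
    "tsrt_slower_group": "SZP",
    "rank_method": "nearest",
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def load_config(path: str | Path | None = None,
                overrides: Mapping[str, Any] | None = None) -> dict:
    """Merge defaults, an optional YAML file and explicit overrides."""
    config = deepcopy(DEFAULT_CONFIG)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if not isinstance(loaded, Mapping) or not loaded:
            raise PipelineError("config", f"empty or invalid config file {path}")
        _deep_update(config, loaded)
    if overrides:
        _deep_update(config, dict(overrides))
    return config


def _deep_update(base: dict, extra: Mapping) -> None:
    for key, value in extra.items():
        if isinstance(value, Mapping) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value


def _latency_from_config(cfg: Mapping[str, Any]) -> LatencyModel:
    if cfg["kind"] == "constant":
        return LatencyModel.constant(float(cfg["value_ms"]))
    return LatencyModel.exgaussian(float(cfg["mu_ms"]), float(cfg["sigma_ms"]),
                                   float(cfg["tau_ms"]))


def race_params_from_config(cfg: Mapping[str, Any]) -> RaceParameters:
    return RaceParameters(
        go1=_latency_from_config(cfg["go1"]),
        go2=_latency_from_config(cfg["go2"]),
        stop=_latency_from_config(cfg["stop"]),
        p_trigger_failure=float(cfg.get("p_trigger_failure", 0.0)),
    )


def classify_simulated(dataset: BehavioralDataset,
                       exclusion_floor_ms: float = 100.0) -> pd.DataFrame:
    """Trial table straight from race outcomes (simulate mode).

    Applies the anticipation exclusion on the array-onset clock; on
    compensated trials the saccade starts at TSD + RT after array onset.
    """
    df = dataset.to_frame()
    onset_rel_array = np.where(df["outcome"] == "compensated",
                               df["tsd_ms"].fillna(0.0) + df["rt_ms"],
                               df["rt_ms"])
    df["excluded"] = onset_rel_array < exclusion_floor_ms
    return df


def classify_detected(dataset: BehavioralDataset, geometry: ArrayGeometry,
                      noise: NoiseModel, rng: np.random.Generator,
                      det_config: DetectionConfig | None = None,
                      cls_config: ClassificationConfig | None = None
                      ) -> pd.DataFrame:
    """Trial table via render → drift-correct → detect → classify."""
    rows = []
    for outcome in dataset.outcomes:
        trace = render_trial_trace(outcome, geometry, noise, rng)
        row = classify_rendered_trial(trace, _ground_truth_dict(outcome),
                                      geometry, det_config, cls_config)
        row["subject"] = dataset.subject
        row["true_outcome"] = outcome.outcome
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: Mapping[str, Any], out_dir: str | Path,
                 seed: int) -> dict:
    """Run the full behavioral pipeline and write the report bundle.

    Writes, under ``out_dir``: the experiment plan, per-subject classified
    trial tables, the subject-summary table, Vincentized RT curves per
    group, and ``report.json`` with group statistics, the consistency
    checks, and the exact config and seed used.  Returns the report dict.
    """
    if not config:
        raise PipelineError("config", "configuration is empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"sacstep {__version__}", f"seed {seed}",
                 f"python {sys.version.split()[0]}"]

    try:
        geometry = ArrayGeometry(**config["geometry"])
        frame_ms = float(config["frame_ms"])
        staircase0 = StaircaseState.from_ms(
            tsd_ms=float(config["staircase"]["start_ms"]), frame_ms=frame_ms,
            step_ms=float(config["staircase"]["step_ms"]))
    except (KeyError, ValueError) as exc:
        raise PipelineError("config", str(exc)) from exc

    root_ss = np.random.SeedSequence(seed)
    plan_rng = np.random.default_rng(root_ss.spawn(1)[0])

    mode = config.get("mode", "simulate")
    if mode not in ("simulate", "detect"):
        raise PipelineError("config", f"unknown mode {mode!r}")

    summaries, labels, trial_tables = [], [], []
    subject_id = 0
    for group_label in sorted(config["groups"]):
        gcfg = config["groups"][group_label]
        try:
            params = race_params_from_config(gcfg)
        except (KeyError, ValueError) as exc:
            raise PipelineError("config", f"group {group_label}: {exc}") from exc
        for _ in range(int(gcfg["n_subjects"])):
            # independent substreams per subject: plan, behavior, rendering
            child = np.random.SeedSequence(entropy=seed,
                                           spawn_key=(1, subject_id))
            plan = build_experiment_plan(
                int(config["sessions"]), int(config["trials_per_session"]),
                tuple(config["proportions"]), geometry,
                np.random.default_rng(child.spawn(1)[0]))
            dataset = simulate_subject(
                params, plan, staircase0,
                np.random.default_rng(child.spawn(1)[0]), subject=subject_id)
            if mode == "detect":
                noise = NoiseModel(
                    fixation_sd_deg=float(config["noise"]["fixation_sd_deg"]),
                    drift_offset_deg=tuple(config["noise"]["drift_offset_deg"]),
                    blink_rate_per_trial=float(config["noise"]["blink_rate_per_trial"]),
                    blink_duration_ms=float(config["noise"]["blink_duration_ms"]))
                table = classify_detected(
                    dataset, geometry, noise,
                    np.random.default_rng(child.spawn(1)[0]))
            else:
                table = classify_simulated(dataset)
            table["subject"] = subject_id
            table["group"] = group_label
            trial_tables.append(table)
            try:
                summaries.append(summarize_subject(
                    table, rank_method=config.get("rank_method", "nearest")))
            except Exception as exc:
                raise PipelineError("summarize",
                                    f"subject {subject_id}: {exc}") from exc
            labels.append(group_label)
            subject_id += 1

    trials = pd.concat(trial_tables, ignore_index=True)
    trials.to_csv(out_dir / "trials.tsv", sep="\t", index=False)
    summary_table = summaries_to_frame(summaries, labels)
    summary_table.to_csv(out_dir / "subject_summaries.tsv", sep="\t", index=False)

    # Vincentized curves per group and condition
    vinc_rows = []
    for group_label in sorted(set(labels)):
        idx = [i for i, l in enumerate(labels) if l == group_label]
        for condition, attr in (("no_step", "no_step_rts"),
                                ("compensated", "compensated_rts"),
                                ("noncompensated", "noncompensated_rts")):
            per_subj = [getattr(summaries[i], attr) for i in idx]
            try:
                v = vincentize(per_subj)
            except Exception:
                continue
            for b in range(v.n_bins):
                vinc_rows.append({"group": group_label, "condition": condition,
                                  "decile": b + 1,
                                  "mean_rt_ms": v.group_means[b],
                                  "sem_ms": v.group_sem[b]})
    pd.DataFrame(vinc_rows).to_csv(out_dir / "vincentized.tsv", sep="\t",
                                   index=False)

    # group statistics
    report: dict[str, Any] = {
        "version": __version__, "seed": seed, "config": _jsonable(config),
        "n_subjects": subject_id,
    }
    try:
        group_stats: dict[str, Any] = {}
        for group_label in sorted(set(labels)):
            sub = summary_table[summary_table["group"] == group_label]
            group_stats[group_label] = {
                "n": int(len(sub)),
                "tsrt_ms_mean": float(sub["tsrt_ms"].mean()),
                "tsrt_ms_sd": float(sub["tsrt_ms"].std(ddof=1)),
                "no_step_rt_ms_mean": float(sub["no_step_rt_ms"].mean()),
                "noncompensated_rt_ms_mean": float(sub["noncompensated_rt_ms"].mean()),
                "p_noncompensated_mean": float(sub["p_noncompensated"].mean()),
            }
        report["groups"] = group_stats
        report["staircase_check"] = {
            "mean_p_noncompensated": float(summary_table["p_noncompensated"].mean()),
            "target": 0.5,
        }
        if len(set(labels)) == 2:
            report["tsrt_test"] = compare_tsrt_table(
                summary_table, config.get("tsrt_slower_group", sorted(set(labels))[1]))
            long = summary_table.melt(
                id_vars=["subject", "group"],
                value_vars=["no_step_rt_ms", "compensated_rt_ms",
                            "noncompensated_rt_ms"],
                var_name="condition", value_name="rt_ms")
            report["rt_anova"] = rt_mixed_anova(long).to_dict(orient="records")
        report["consistency"] = [
            race_consistency_report(s) for s in summaries[:1]]  # exemplar subject
        report["consistency_all_subjects"] = {
            "n_noncomp_faster": int(sum(
                s.mean_rt("noncompensated") <= s.mean_rt("no_step")
                for s in summaries)),
            "n_subjects": len(summaries),
        }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("report", str(exc)) from exc

    (out_dir / "report.json").write_text(json.dumps(report, indent=1,
                                                    sort_keys=True))
    log_lines.append(f"subjects {subject_id}, mode {mode}")
    (out_dir / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    return report


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
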