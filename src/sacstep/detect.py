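"""Eye-trace processing: drift correction, velocity, saccade detection,
online positional classification and RT extraction.

The processing chain mirrors standard oculomotor practice for low-rate
(60 Hz) video eye tracking: correct slow calibration drift against the
pre-array fixation, differentiate position to velocity, low-pass filter
with a zero-phase Butterworth, mark supra-threshold velocity runs as
saccades, and classify redirect trials by the direction of the first
excursion out of the fixation window.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .gaze import GazeTrace, read_trace
from .task import ArrayGeometry, TrialSpec


class DetectionError(ValueError):
    """Raised when a trace cannot be processed consistently."""


@dataclass(frozen=True)
class DetectionConfig:
    """Velocity filtering and event-marking parameters.

    The nominal 40 Hz low-pass cutoff exceeds the Nyquist frequency of
    60 Hz data; the effective cutoff is clamped to 0.9 x Nyquist (with a
    warning) so the same configuration works at any sample rate.
    The 30 deg/s threshold is a deliberately liberal criterion for video
    eye tracking.
    """

    filter_order: int = 5
    cutoff_hz: float = 40.0
    velocity_threshold_deg_s: float = 30.0
    min_event_samples: int = 2
    merge_gap_ms: float = 20.0
    max_interp_gap_ms: float = 100.0

    def __post_init__(self) -> None:
        if self.filter_order < 1 or self.velocity_threshold_deg_s <= 0:
            raise ValueError("invalid detection configuration")


@dataclass(frozen=True)
class ClassificationConfig:
    """Online positional classification rule for redirect trials.

    Gaze must leave a 2 deg window around fixation for at least two
    consecutive samples (33 ms at 60 Hz), no earlier than 100 ms after
    array onset, and head within 45 deg of the fixation->target vector to
    count as a response to that target.
    """

    window_deg: float = 2.0
    min_consecutive_samples: int = 2
    latency_floor_ms: float = 100.0
    direction_halfangle_deg: float = 45.0

    def __post_init__(self) -> None:
        if min(self.window_deg, self.min_consecutive_samples,
               self.latency_floor_ms, self.direction_halfangle_deg) <= 0:
            raise ValueError("classification parameters must be positive")


@dataclass(frozen=True)
class SaccadeEvent:
    onset_ms: float
    offset_ms: float
    amplitude_deg: float
    direction_deg: float
    peak_velocity_deg_s: float

    def __post_init__(self) -> None:
        if self.offset_ms <= self.onset_ms or self.amplitude_deg < 0:
            raise ValueError("invalid saccade event")


def drift_correct(trace: GazeTrace, array_onset_ms: float | None = None,
                  half_window_ms: float = 50.0) -> GazeTrace:
    """Subtract the mean eye position around array onset from the trace.

    The reference window spans ``array_onset +/- half_window_ms``; only
    valid samples contribute.  If the window holds no valid sample the
    trace is returned uncorrected with a warning (the flagged condition).
    Idempotent on offset-only traces: after one application the window
    mean is zero.
    """
    onset = trace.array_onset_ms if array_onset_ms is None else array_onset_ms
    in_window = (trace.t_ms >= onset - half_window_ms) & \
                (trace.t_ms <= onset + half_window_ms)
    usable = in_window & trace.valid
    if not usable.any():
        warnings.warn("no valid samples in drift-correction window; "
                      "trace returned uncorrected")
        return trace
    mx = float(trace.x_deg[usable].mean())
    my = float(trace.y_deg[usable].mean())
    return replace(trace, x_deg=trace.x_deg - mx, y_deg=trace.y_deg - my)


def _interpolate_invalid(trace: GazeTrace, max_gap_ms: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fill invalid spans <= max_gap_ms by linear interpolation.

    Returns (x, y, masked) where ``masked`` flags samples in spans too long
    to interpolate; events overlapping masked samples are discarded later.
    """
    x = trace.x_deg.copy()
    y = trace.y_deg.copy()
    valid = trace.valid
    masked = np.zeros(len(x), dtype=bool)
    if valid.all():
        return x, y, masked
    if not valid.any():
        return x, y, np.ones(len(x), dtype=bool)
    t = trace.t_ms
    x[~valid] = np.interp(t[~valid], t[valid], x[valid])
    y[~valid] = np.interp(t[~valid], t[valid], y[valid])
    # find invalid runs and mask the long ones
    idx = np.flatnonzero(~valid)
    splits = np.flatnonzero(np.diff(idx) > 1)
    dt = 1000.0 / trace.sample_rate_hz
    for run in np.split(idx, splits + 1):
        if len(run) * dt > max_gap_ms:
            masked[run] = True
    return x, y, masked


def effective_cutoff_hz(cutoff_hz: float, sample_rate_hz: float) -> float:
    """Clamp the filter cutoff to 0.9 x Nyquist, warning when it binds."""
    nyquist = sample_rate_hz / 2.0
    if cutoff_hz >= nyquist:
        clamped = 0.9 * nyquist
        warnings.warn(
            f"cutoff {cutoff_hz} Hz >= Nyquist ({nyquist} Hz) at "
            f"{sample_rate_hz} Hz sampling; clamping to {clamped:.1f} Hz")
        return clamped
    return cutoff_hz


def compute_velocity(trace: GazeTrace, config: DetectionConfig | None = None
                     ) -> np.ndarray:
    """Low-pass-filtered eye speed, deg/s, aligned to the trace samples.

    Position is differentiated by central differences; each velocity
    component is filtered forward-backward (zero phase, so saccade onsets
    do not shift) with a Butterworth low-pass, and the speed magnitude is
    returned.
    """
    if config is None:
        config = DetectionConfig()
    padlen = 3 * (2 * config.filter_order + 1)
    if trace.n_samples <= padlen:
        raise DetectionError(f"trace too short to filter ({trace.n_samples} samples)")
    x, y, _ = _interpolate_invalid(trace, config.max_interp_gap_ms)
    t_s = trace.t_ms / 1000.0
    vx = np.gradient(x, t_s)
    vy = np.gradient(y, t_s)
    cutoff = effective_cutoff_hz(config.cutoff_hz, trace.sample_rate_hz)
    sos = signal.butter(config.filter_order, cutoff, btype="low",
                        fs=trace.sample_rate_hz, output="sos")
    vx = signal.sosfiltfilt(sos, vx)
    vy = signal.sosfiltfilt(sos, vy)
    return np.hypot(vx, vy)


def detect_saccades(velocity: np.ndarray, trace: GazeTrace,
                    config: DetectionConfig | None = None) -> list[SaccadeEvent]:
    """Mark maximal supra-threshold velocity runs as saccade events.

    Runs separated by less than ``merge_gap_ms`` are merged, runs shorter
    than ``min_event_samples`` are discarded, and events overlapping
    unrecoverable invalid spans are dropped (the automated stand-in for
    manual artifact rejection).
    """
    if config is None:
        config = DetectionConfig()
    if len(velocity) != trace.n_samples:
        raise DetectionError("velocity not aligned to trace")
    above = velocity > config.velocity_threshold_deg_s
    if not above.any():
        return []
    _, _, masked = _interpolate_invalid(trace, config.max_interp_gap_ms)
    dt_ms = 1000.0 / trace.sample_rate_hz

    idx = np.flatnonzero(above)
    splits = np.flatnonzero(np.diff(idx) > 1)
    runs = [(r[0], r[-1]) for r in np.split(idx, splits + 1)]

    merged: list[list[int]] = [list(runs[0])]
    for start, stop in runs[1:]:
        if (start - merged[-1][1]) * dt_ms < config.merge_gap_ms:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])

    events: list[SaccadeEvent] = []
    for start, stop in merged:
        if stop - start + 1 < config.min_event_samples:
            continue
        if masked[start:stop + 1].any():
            continue
        dx = trace.x_deg[stop] - trace.x_deg[start]
        dy = trace.y_deg[stop] - trace.y_deg[start]
        events.append(SaccadeEvent(
            onset_ms=float(trace.t_ms[start]),
            offset_ms=float(trace.t_ms[stop]),
            amplitude_deg=float(np.hypot(dx, dy)),
            direction_deg=float(np.degrees(np.arctan2(dy, dx)) % 360.0),
            peak_velocity_deg_s=float(velocity[start:stop + 1].max()),
        ))
    return events


def _angle_to(target_xy: tuple[float, float]) -> float:
    return float(np.degrees(np.arctan2(target_xy[1], target_xy[0])) % 360.0)


def _angular_distance(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def classify_trial_online(trace: GazeTrace, trial: TrialSpec,
                          geometry: ArrayGeometry,
                          config: ClassificationConfig | None = None) -> str:
    """Positional online classification of a redirect trial.

    The first run of at least ``min_consecutive_samples`` valid samples
    outside the fixation window, starting later than the latency floor
    after array onset, decides the trial: excursion toward T2 ->
    ``compensated``, toward T1 -> ``noncompensated``, toward neither (or
    no qualifying excursion, e.g. a blink) -> ``indeterminate``.
    """
    if config is None:
        config = ClassificationConfig()
    if trial.trial_type != "redirect" or trial.t2_index is None:
        raise DetectionError("online classification applies to redirect trials")

    t0 = trace.array_onset_ms + config.latency_floor_ms
    eligible = (trace.t_ms >= t0) & trace.valid
    outside = (np.hypot(trace.x_deg, trace.y_deg) > config.window_deg) & eligible
    if not outside.any():
        return "indeterminate"
    idx = np.flatnonzero(outside)
    splits = np.flatnonzero(np.diff(idx) > 1)
    for run in np.split(idx, splits + 1):
        if len(run) < config.min_consecutive_samples:
            continue
        k = run[: config.min_consecutive_samples]
        direction = float(np.degrees(np.arctan2(
            trace.y_deg[k].mean(), trace.x_deg[k].mean())) % 360.0)
        to_t1 = _angular_distance(direction, _angle_to(geometry.position_xy(trial.t1_index)))
        to_t2 = _angular_distance(direction, _angle_to(geometry.position_xy(trial.t2_index)))
        if to_t2 <= config.direction_halfangle_deg and to_t2 <= to_t1:
            return "compensated"
        if to_t1 <= config.direction_halfangle_deg:
            return "noncompensated"
        return "indeterminate"
    return "indeterminate"


def extract_rt(events: Sequence[SaccadeEvent], trial: TrialSpec,
               tsd_ms: Optional[float], outcome_class: str,
               array_onset_ms: float,
               exclusion_floor_ms: float = 100.0) -> tuple[float, bool]:
    """Saccade latency per the task's reference conventions.

    No-step, noncompensated and follow latencies are measured from array
    onset; compensated latencies from T2 onset (array onset + TSD).
    Saccades initiated earlier than 100 ms after array onset are flagged
    as anticipations and excluded from analysis.
    """
    if outcome_class == "indeterminate":
        raise DetectionError("cannot extract RT from an indeterminate trial")
    post = [e for e in events if e.onset_ms >= array_onset_ms]
    if not post:
        raise DetectionError("classified trial has no saccade event after array onset")
    onset_rel_array = post[0].onset_ms - array_onset_ms
    if outcome_class == "compensated":
        if tsd_ms is None:
            raise DetectionError("compensated trial needs a TSD for the T2 clock")
        rt = onset_rel_array - tsd_ms
    else:
        rt = onset_rel_array
    return float(rt), bool(onset_rel_array < exclusion_floor_ms)


# ---------------------------------------------------------------------------
# Batch interface: traces on disk -> classified trial table.

def classify_rendered_trial(trace: GazeTrace, truth: dict,
                            geometry: ArrayGeometry,
                            det_config: DetectionConfig | None = None,
                            cls_config: ClassificationConfig | None = None) -> dict:
    """Full offline pipeline for one rendered trial.

    Returns a row with the detected classification, extracted RT and the
    exclusion flag; redirect trials are classified positionally, other
    types keep their planned label.
    """
    trial = TrialSpec(trial_type=truth["trial_type"], t1_index=truth["t1_index"],
                      t2_index=truth["t2_index"], fixation_ms=trace.array_onset_ms,
                      session=truth["session"], trial_index=truth["trial_index"])
    corrected = drift_correct(trace)
    velocity = compute_velocity(corrected, det_config)
    events = detect_saccades(velocity, corrected, det_config)
    tsd = truth.get("tsd_ms")
    if trial.trial_type == "redirect":
        label = classify_trial_online(corrected, trial, geometry, cls_config)
    elif trial.trial_type == "no_step":
        label = "no_step_saccade"
    else:
        label = "follow_saccade"
    row = {
        "session": trial.session,
        "trial_index": trial.trial_index,
        "trial_type": trial.trial_type,
        "tsd_ms": np.nan if tsd is None else tsd,
        "outcome": label,
        "n_events": len(events),
        "rt_ms": np.nan,
        "excluded": False,
    }
    rt_class = label if trial.trial_type == "redirect" else label
    if label != "indeterminate" and events:
        try:
            rt, excluded = extract_rt(events, trial, tsd, rt_class,
                                      trace.array_onset_ms)
        except DetectionError:
            rt, excluded = np.nan, True
        row["rt_ms"] = rt
        row["excluded"] = excluded
    elif label != "indeterminate":
        row["excluded"] = True
    return row


def detect_directory(traces_dir: str | Path, geometry: ArrayGeometry,
                     det_config: DetectionConfig | None = None,
                     cls_config: ClassificationConfig | None = None) -> pd.DataFrame:
    """Run the offline pipeline over every manifest in a trace directory."""
    traces_dir = Path(traces_dir)
    rows = []
    manifests = sorted(traces_dir.glob("*_manifest.json"))
    if not manifests:
        raise DetectionError(f"no manifest files found in {traces_dir}")
    for mpath in manifests:
        manifest = json.loads(mpath.read_text())
        for entry in manifest["traces"]:
            trace, truth = read_trace(traces_dir / entry["file"])
            if truth is None:
                raise DetectionError(f"trace {entry['file']} has no sidecar metadata")
            row = classify_rendered_trial(trace, truth, geometry,
                                          det_config, cls_config)
            row["subject"] = manifest["subject"]
            row["true_outcome"] = truth["outcome"]
            rows.append(row)
    return pd.DataFrame(rows)
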