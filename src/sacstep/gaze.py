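"""Synthetic 60 Hz gaze traces for simulated trials.

Renders TrialOutcomes into 2D eye-position traces with known ground truth,
so the detection pipeline can be scored exactly.  Fixation is at the
origin; saccades follow a logistic position ramp whose duration scales
with amplitude (main-sequence approximation: 2.2 ms/deg + 21 ms).  The
noise model emulates the artifacts real recordings carry and that the
offline analysis must survive: Gaussian camera/fixation noise, a constant
calibration drift offset, and blinks encoded as invalid samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .race import BehavioralDataset, TrialOutcome
from .task import ArrayGeometry

MAIN_SEQUENCE_SLOPE_MS_PER_DEG = 2.2
MAIN_SEQUENCE_INTERCEPT_MS = 21.0


@dataclass(frozen=True)
class GazeTrace:
    """Uniformly sampled 2D eye position with validity flags and markers.

    ``t_ms`` spans the full trial (default 4 s at 60 Hz → 240 samples);
    ``valid`` is False during blinks/dropouts.  ``array_onset_ms`` marks
    search-array appearance (end of the fixation period) and
    ``step_onset_ms`` the target step on redirect trials.
    """

    t_ms: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    valid: np.ndarray
    array_onset_ms: float
    step_onset_ms: Optional[float] = None
    sample_rate_hz: float = 60.0

    def __post_init__(self) -> None:
        n = len(self.t_ms)
        if not (len(self.x_deg) == len(self.y_deg) == len(self.valid) == n):
            raise ValueError("trace arrays must have equal length")
        if n >= 2:
            dt = np.diff(self.t_ms)
            if not np.allclose(dt, dt[0]):
                raise ValueError("trace must be uniformly sampled")
        if not (self.t_ms[0] <= self.array_onset_ms <= self.t_ms[-1]):
            raise ValueError("array onset outside trace span")

    @property
    def n_samples(self) -> int:
        return len(self.t_ms)

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.x_deg, self.y_deg])


@dataclass(frozen=True)
class NoiseModel:
    """Recording-artifact model for synthetic traces.

    fixation_sd_deg — isotropic Gaussian position noise on every sample;
    drift_offset_deg — constant 2D calibration offset added to the trace;
    blink_rate_per_trial — expected number of blinks (Poisson);
    blink_duration_ms — length of each invalid span.
    """

    fixation_sd_deg: float = 0.15
    drift_offset_deg: tuple[float, float] = (0.0, 0.0)
    blink_rate_per_trial: float = 0.2
    blink_duration_ms: float = 150.0
    blink_excursion_deg: float = 0.0  # optional large artifact excursion mode

    def __post_init__(self) -> None:
        if (self.fixation_sd_deg < 0 or self.blink_rate_per_trial < 0
                or self.blink_duration_ms < 0 or self.blink_excursion_deg < 0):
            raise ValueError("noise parameters must be non-negative")


def noise_free() -> NoiseModel:
    return NoiseModel(fixation_sd_deg=0.0, drift_offset_deg=(0.0, 0.0),
                      blink_rate_per_trial=0.0)


def saccade_duration_ms(amplitude_deg: float) -> float:
    """Main-sequence amplitude/duration relation."""
    return MAIN_SEQUENCE_SLOPE_MS_PER_DEG * amplitude_deg + MAIN_SEQUENCE_INTERCEPT_MS


def _logistic_ramp(t_ms: np.ndarray, onset_ms: float, duration_ms: float) -> np.ndarray:
    """Smooth 0→1 position ramp over [onset, onset + duration].

    A logistic in normalized time, rescaled so the ramp is exactly 0 before
    onset and exactly 1 after offset (piecewise-constant outside the
    saccade, as required for zero inter-saccadic velocity).
    """
    u = (t_ms - onset_ms) / duration_ms
    k = 12.0
    raw = 1.0 / (1.0 + np.exp(-k * (np.clip(u, 0.0, 1.0) - 0.5)))
    lo = 1.0 / (1.0 + np.exp(k / 2.0))
    ramp = (raw - lo) / (1.0 - 2.0 * lo)
    ramp[u <= 0.0] = 0.0
    ramp[u >= 1.0] = 1.0
    return ramp


def render_trial_trace(
    outcome: TrialOutcome,
    geometry: ArrayGeometry,
    noise: NoiseModel,
    rng: np.random.Generator,
    trial_duration_ms: float = 4000.0,
    sample_rate_hz: float = 60.0,
) -> GazeTrace:
    """Render one trial's outcome into a gaze trace.

    The eye rests at fixation until the first saccade, whose onset is the
    outcome's RT converted to the array-onset clock (compensated RTs are
    T2-onset-referenced, so the step delay is added back).  Noncompensated
    and follow trials carry a second saccade to T2.
    """
    trial = outcome.trial
    n = int(round(trial_duration_ms * sample_rate_hz / 1000.0))
    t = np.arange(n) * (1000.0 / sample_rate_hz)
    array_onset = trial.fixation_ms
    step_onset = None if outcome.tsd_ms is None else array_onset + outcome.tsd_ms

    # first saccade onset on the trace clock
    if outcome.outcome == "compensated":
        first_onset = step_onset + outcome.rt_ms
    else:
        first_onset = array_onset + outcome.rt_ms
    if first_onset >= trial_duration_ms:
        raise ValueError("saccade onset beyond trace span")

    targets = [np.asarray(geometry.position_xy(outcome.first_target))]
    onsets = [first_onset]
    if outcome.outcome in ("noncompensated", "follow_saccade") \
            and outcome.corrective_rt_ms is not None:
        assert trial.t2_index is not None
        targets.append(np.asarray(geometry.position_xy(trial.t2_index)))
        onsets.append(array_onset + outcome.corrective_rt_ms)

    pos = np.zeros((n, 2))
    current = np.zeros(2)
    prev_offset = -np.inf
    for onset, target in zip(onsets, targets):
        onset = max(onset, prev_offset)  # saccades cannot overlap
        amp = float(np.linalg.norm(target - current))
        dur = saccade_duration_ms(amp)
        ramp = _logistic_ramp(t, onset, dur)
        pos = pos + np.outer(ramp, target - current)
        current = target
        prev_offset = onset + dur

    pos = pos + np.asarray(noise.drift_offset_deg)
    if noise.fixation_sd_deg > 0:
        pos = pos + rng.normal(0.0, noise.fixation_sd_deg, size=pos.shape)

    valid = np.ones(n, dtype=bool)
    n_blinks = rng.poisson(noise.blink_rate_per_trial) if noise.blink_rate_per_trial else 0
    blink_samples = max(1, int(round(noise.blink_duration_ms * sample_rate_hz / 1000.0)))
    for _ in range(n_blinks):
        start = int(rng.integers(0, max(1, n - blink_samples)))
        stop = min(n, start + blink_samples)
        valid[start:stop] = False
        if noise.blink_excursion_deg > 0:
            direction = rng.normal(size=2)
            direction /= np.linalg.norm(direction)
            pos[start:stop] += noise.blink_excursion_deg * direction
        else:
            # camera loses the eye: hold last valid position
            hold = pos[start - 1] if start > 0 else pos[0]
            pos[start:stop] = hold

    return GazeTrace(t_ms=t, x_deg=pos[:, 0], y_deg=pos[:, 1], valid=valid,
                     array_onset_ms=array_onset, step_onset_ms=step_onset,
                     sample_rate_hz=sample_rate_hz)


def inject_drift(trace: GazeTrace, offset_deg: tuple[float, float]) -> GazeTrace:
    """Shift the whole trace by a constant offset; markers unchanged."""
    return replace(trace,
                   x_deg=trace.x_deg + offset_deg[0],
                   y_deg=trace.y_deg + offset_deg[1])


# ---------------------------------------------------------------------------
# Trace file I/O: one delimited table per trial + a JSON sidecar with
# markers and simulator ground truth, indexed by a manifest.

def write_trace(trace: GazeTrace, path: str | Path,
                ground_truth: dict | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame({
        "t_ms": trace.t_ms,
        "x_deg": trace.x_deg,
        "y_deg": trace.y_deg,
        "valid": trace.valid.astype(int),
    })
    df.to_csv(path, sep="\t", index=False)
    sidecar = {
        "sample_rate_hz": trace.sample_rate_hz,
        "array_onset_ms": trace.array_onset_ms,
        "step_onset_ms": trace.step_onset_ms,
        "ground_truth": ground_truth,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_trace(path: str | Path) -> tuple[GazeTrace, dict | None]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    trace = GazeTrace(
        t_ms=df["t_ms"].to_numpy(float),
        x_deg=df["x_deg"].to_numpy(float),
        y_deg=df["y_deg"].to_numpy(float),
        valid=df["valid"].to_numpy(bool),
        array_onset_ms=float(sidecar["array_onset_ms"]),
        step_onset_ms=(None if sidecar["step_onset_ms"] is None
                       else float(sidecar["step_onset_ms"])),
        sample_rate_hz=float(sidecar["sample_rate_hz"]),
    )
    return trace, sidecar.get("ground_truth")


def _ground_truth_dict(outcome: TrialOutcome) -> dict:
    t = outcome.trial
    return {
        "trial_type": t.trial_type,
        "outcome": outcome.outcome,
        "rt_ms": outcome.rt_ms,
        "tsd_ms": outcome.tsd_ms,
        "corrective_rt_ms": outcome.corrective_rt_ms,
        "t1_index": t.t1_index,
        "t2_index": t.t2_index,
        "session": t.session,
        "trial_index": t.trial_index,
    }


def render_dataset(dataset: BehavioralDataset, geometry: ArrayGeometry,
                   noise: NoiseModel, rng: np.random.Generator,
                   out_dir: str | Path) -> Path:
    """Render every trial of a dataset to disk; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, outcome in enumerate(dataset.outcomes):
        name = f"subj{dataset.subject:03d}_trial{i:04d}.tsv"
        trace = render_trial_trace(outcome, geometry, noise, rng)
        write_trace(trace, out_dir / name, ground_truth=_ground_truth_dict(outcome))
        entries.append({"trial": i, "file": name})
    manifest = out_dir / f"subj{dataset.subject:03d}_manifest.json"
    manifest.write_text(json.dumps(
        {"subject": dataset.subject, "traces": entries}, indent=1))
    return manifest
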