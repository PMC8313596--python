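"""Experiment plans and the adaptive target-step-delay staircase.

The search-step task interleaves three trial types — *no-step* (a single
red target among distractors; saccade to it), *redirect* (the target jumps
to a new location after a target-step delay, TSD; the planned saccade must
be inhibited and redirected) and *follow* (two targets; look at each in
succession).  The TSD on redirect trials is adjusted with a one-up/one-down
staircase so that inhibition succeeds on roughly half of the redirect
trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

TRIAL_TYPES = ("no_step", "redirect", "follow")

#: Staircase outcomes as reported by the online classifier.
STAIRCASE_OUTCOMES = ("compensated", "noncompensated", "indeterminate")


class ConfigurationError(ValueError):
    """Raised for invalid experiment or staircase configuration."""


class GeometryError(ValueError):
    """Raised when the stimulus geometry cannot satisfy task constraints."""


@dataclass(frozen=True)
class ArrayGeometry:
    """Circular search array: equidistant, evenly spaced elements.

    Parameters
    ----------
    n_positions:
        Number of array elements (≥ 2).
    eccentricity_deg:
        Radial distance of every element from fixation, degrees of
        visual angle.
    element_size_deg:
        Diameter of each element, degrees.
    """

    n_positions: int = 8
    eccentricity_deg: float = 9.0
    element_size_deg: float = 0.7

    def __post_init__(self) -> None:
        if self.n_positions < 2:
            raise GeometryError("array needs at least 2 positions")
        if self.eccentricity_deg <= 0:
            raise GeometryError("eccentricity must be positive")

    @property
    def position_angles_deg(self) -> np.ndarray:
        """Polar angle of each position, degrees, evenly spaced from 0."""
        return np.arange(self.n_positions) * (360.0 / self.n_positions)

    def position_xy(self, index: int) -> tuple[float, float]:
        """Cartesian position (x, y) in degrees of visual angle."""
        theta = math.radians(self.position_angles_deg[index])
        r = self.eccentricity_deg
        return (r * math.cos(theta), r * math.sin(theta))

    def angular_separation_deg(self, i: int, j: int) -> float:
        """Smallest angle between two array positions, degrees in [0, 180]."""
        angles = self.position_angles_deg
        d = abs(angles[i] - angles[j]) % 360.0
        return min(d, 360.0 - d)


@dataclass(frozen=True)
class TrialSpec:
    """One planned trial.

    ``t2_index`` is present exactly when the trial is not a no-step trial,
    and then lies at least 90° of polar angle away from ``t1_index``.
    """

    trial_type: str
    t1_index: int
    t2_index: Optional[int]
    fixation_ms: float
    session: int
    trial_index: int

    def __post_init__(self) -> None:
        if self.trial_type not in TRIAL_TYPES:
            raise ConfigurationError(f"unknown trial type {self.trial_type!r}")
        if (self.t2_index is None) != (self.trial_type == "no_step"):
            raise ConfigurationError("t2 must be present iff trial type is not no_step")
        if not 1000.0 <= self.fixation_ms <= 2000.0:
            raise ConfigurationError("fixation duration must lie in [1000, 2000] ms")


@dataclass(frozen=True)
class SessionPlan:
    """Ordered trials of one scanning session plus interleaved rest blocks.

    ``rest_blocks`` holds (insertion index into the trial sequence,
    duration in seconds) pairs; six 10 s fixation-only blocks per session.
    """

    trials: tuple[TrialSpec, ...]
    rest_blocks: tuple[tuple[int, float], ...]
    session_duration_target_s: float = 300.0


@dataclass(frozen=True)
class StaircaseState:
    """One-up/one-down TSD staircase state, on the display frame grid.

    The TSD is stored as an integer number of display frames so that every
    delay is an exact multiple of the frame duration.  At 60 Hz the default
    step of 4 frames is ~67 ms and the conventional 100 ms start is 6 frames.
    """

    tsd_frames: int
    frame_ms: float = 1000.0 / 60.0
    step_frames: int = 4
    min_frames: int = 1

    def __post_init__(self) -> None:
        if self.tsd_frames < self.min_frames:
            raise ConfigurationError("tsd_frames below min_frames")
        if self.step_frames <= 0 or self.min_frames < 0:
            raise ConfigurationError("invalid staircase step/floor")

    @property
    def tsd_ms(self) -> float:
        return self.tsd_frames * self.frame_ms

    @classmethod
    def from_ms(cls, tsd_ms: float = 100.0, frame_ms: float = 1000.0 / 60.0,
                step_ms: float = 67.0, min_frames: int = 1) -> "StaircaseState":
        """Build a state from millisecond targets, rounding to the frame grid."""
        return cls(
            tsd_frames=max(min_frames, round(tsd_ms / frame_ms)),
            frame_ms=frame_ms,
            step_frames=max(1, round(step_ms / frame_ms)),
            min_frames=min_frames,
        )


def staircase_update(state: StaircaseState, outcome: str) -> StaircaseState:
    """Advance the one-up/one-down staircase after one redirect trial.

    A *compensated* trial (successful inhibition) makes the next step
    harder (TSD + step); a *noncompensated* trial makes it easier
    (TSD − step, clamped at the floor); an *indeterminate* trial — the
    online classifier could not attribute gaze to either target, e.g.
    because of a blink — leaves the TSD unchanged.
    """
    if outcome not in STAIRCASE_OUTCOMES:
        raise ConfigurationError(f"unknown staircase outcome {outcome!r}")
    if outcome == "compensated":
        frames = state.tsd_frames + state.step_frames
    elif outcome == "noncompensated":
        frames = max(state.min_frames, state.tsd_frames - state.step_frames)
    else:
        frames = state.tsd_frames
    return replace(state, tsd_frames=frames)


def largest_remainder_counts(total: int, proportions: Sequence[float]) -> list[int]:
    """Apportion ``total`` into integer counts by the largest-remainder rule.

    Floors of ``total * p`` are assigned first; leftover units go to the
    entries with the largest fractional remainders (ties broken by position,
    deterministically).
    """
    if total <= 0:
        raise ConfigurationError("total trial count must be positive")
    props = np.asarray(proportions, dtype=float)
    if props.min() < 0 or abs(props.sum() - 1.0) > 1e-9:
        raise ConfigurationError("proportions must be non-negative and sum to 1")
    ideal = total * props
    counts = np.floor(ideal).astype(int)
    remainder = int(total - counts.sum())
    if remainder:
        order = np.argsort(-(ideal - counts), kind="stable")
        counts[order[:remainder]] += 1
    return counts.tolist()


def eligible_t2_indices(geometry: ArrayGeometry, t1_index: int,
                        min_separation_deg: float = 90.0) -> list[int]:
    """Positions at least ``min_separation_deg`` of polar angle from T1."""
    return [
        j for j in range(geometry.n_positions)
        if j != t1_index
        and geometry.angular_separation_deg(t1_index, j) >= min_separation_deg
    ]


def sample_targets(geometry: ArrayGeometry, trial_type: str,
                   rng: np.random.Generator,
                   min_separation_deg: float = 90.0) -> tuple[int, Optional[int]]:
    """Draw T1 (uniform) and, on step/follow trials, a T2 at ≥ 90° from T1.

    The separation constraint discourages averaging saccades that would
    land midway between the two target locations.
    """
    t1 = int(rng.integers(geometry.n_positions))
    if trial_type == "no_step":
        return t1, None
    eligible = eligible_t2_indices(geometry, t1, min_separation_deg)
    if not eligible:
        raise GeometryError(
            f"no position lies >= {min_separation_deg} deg from position {t1}"
        )
    return t1, int(eligible[rng.integers(len(eligible))])


def _rest_block_indices(n_trials: int, n_blocks: int = 6) -> tuple[int, ...]:
    """Evenly spaced interior insertion points for rest blocks."""
    pts = np.linspace(0, n_trials, n_blocks + 2)[1:-1]
    return tuple(int(round(p)) for p in pts)


def build_experiment_plan(
    n_sessions: int,
    trials_per_session: int,
    proportions: Sequence[float] = (0.30, 0.40, 0.30),
    geometry: ArrayGeometry | None = None,
    rng: np.random.Generator | None = None,
    n_rest_blocks: int = 6,
    rest_block_s: float = 10.0,
) -> list[SessionPlan]:
    """Build the full experiment: randomized trial order, exact type counts.

    ``proportions`` gives the (no_step, redirect, follow) fractions; the
    per-type totals over the whole experiment follow the largest-remainder
    allocation, so the standard configuration of 4 sessions × 60 trials at
    (0.30, 0.40, 0.30) yields exactly 72 / 96 / 72 trials.  Trial order is
    randomized over the full experiment, fixation durations are uniform on
    [1000, 2000] ms, and each session carries six 10 s rest blocks.
    """
    if geometry is None:
        geometry = ArrayGeometry()
    if rng is None:
        rng = np.random.default_rng()
    if n_sessions <= 0 or trials_per_session <= 0:
        raise ConfigurationError("need at least one session and one trial")
    if len(proportions) != len(TRIAL_TYPES):
        raise ConfigurationError("proportions must have one entry per trial type")

    total = n_sessions * trials_per_session
    counts = largest_remainder_counts(total, proportions)
    types = np.repeat(np.arange(len(TRIAL_TYPES)), counts)
    rng.shuffle(types)

    sessions: list[SessionPlan] = []
    k = 0
    for s in range(n_sessions):
        trials = []
        for i in range(trials_per_session):
            ttype = TRIAL_TYPES[types[k]]
            t1, t2 = sample_targets(geometry, ttype, rng)
            trials.append(TrialSpec(
                trial_type=ttype,
                t1_index=t1,
                t2_index=t2,
                fixation_ms=float(rng.uniform(1000.0, 2000.0)),
                session=s,
                trial_index=i,
            ))
            k += 1
        rest = tuple((idx, rest_block_s)
                     for idx in _rest_block_indices(trials_per_session, n_rest_blocks))
        sessions.append(SessionPlan(trials=tuple(trials), rest_blocks=rest))
    return sessions


# ---------------------------------------------------------------------------
# Plan I/O: delimited table, one row per trial.

PLAN_COLUMNS = ["session", "trial_index", "trial_type", "t1_index", "t2_index",
                "fixation_ms"]


def plan_to_frame(plans: Sequence[SessionPlan]) -> pd.DataFrame:
    rows = [
        {
            "session": t.session,
            "trial_index": t.trial_index,
            "trial_type": t.trial_type,
            "t1_index": t.t1_index,
            "t2_index": -1 if t.t2_index is None else t.t2_index,
            "fixation_ms": t.fixation_ms,
        }
        for plan in plans for t in plan.trials
    ]
    return pd.DataFrame(rows, columns=PLAN_COLUMNS)


def write_plan(plans: Sequence[SessionPlan], path: str | Path) -> None:
    plan_to_frame(plans).to_csv(path, sep="\t", index=False)


def read_plan(path: str | Path) -> list[SessionPlan]:
    """Read a plan table back; rest blocks are re-derived deterministically."""
    df = pd.read_csv(path, sep="\t")
    sessions = []
    for s, grp in df.groupby("session", sort=True):
        trials = tuple(
            TrialSpec(
                trial_type=row.trial_type,
                t1_index=int(row.t1_index),
                t2_index=None if int(row.t2_index) < 0 else int(row.t2_index),
                fixation_ms=float(row.fixation_ms),
                session=int(row.session),
                trial_index=int(row.trial_index),
            )
            for row in grp.sort_values("trial_index").itertuples()
        )
        rest = tuple((idx, 10.0) for idx in _rest_block_indices(len(trials)))
        sessions.append(SessionPlan(trials=trials, rest_blocks=rest))
    return sessions
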