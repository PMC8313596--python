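"""Independent-race (GO/STOP) behavioral simulator.

Search-step performance is modeled as a race between an observable GO1
process that drives the saccade to the initial target (T1) and a covert
STOP process, triggered by the target step, that cancels it.  The saccade
to T1 is executed iff GO1 finishes before the STOP process; otherwise the
gaze goes directly to the stepped target (T2) with a GO2 latency.  The
simulator couples the race to the one-up/one-down TSD staircase exactly as
the online experiment would, yielding synthetic behavioral datasets with
known ground truth.

Latency conventions follow the task's reaction-time definitions: no-step
and noncompensated RTs are measured from array onset; compensated RTs are
measured from T2 onset (the step).  The STOP finishing time is likewise
measured from T2 onset, so on the array-onset clock the STOP process
finishes at ``TSD + stop_draw``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .task import (
    SessionPlan,
    StaircaseState,
    TrialSpec,
    staircase_update,
)

OUTCOMES = ("no_step_saccade", "compensated", "noncompensated", "follow_saccade")


@dataclass(frozen=True)
class LatencyModel:
    """Latency distribution: degenerate (constant) or ex-Gaussian.

    The ex-Gaussian — a Gaussian(mu, sigma) convolved with an
    Exponential(tau) — is the standard descriptive model for saccadic and
    manual RT distributions; its mean is ``mu + tau``.  Draws are
    truncated at zero by resampling.
    """

    kind: str
    value_ms: float = 0.0
    mu_ms: float = 0.0
    sigma_ms: float = 0.0
    tau_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "exgaussian"):
            raise ValueError(f"unknown latency model kind {self.kind!r}")
        if self.kind == "constant" and self.value_ms < 0:
            raise ValueError("constant latency must be non-negative")
        if self.kind == "exgaussian" and (self.sigma_ms < 0 or self.tau_ms < 0):
            raise ValueError("exgaussian sigma and tau must be non-negative")

    @classmethod
    def constant(cls, value_ms: float) -> "LatencyModel":
        return cls(kind="constant", value_ms=value_ms)

    @classmethod
    def exgaussian(cls, mu_ms: float, sigma_ms: float, tau_ms: float) -> "LatencyModel":
        return cls(kind="exgaussian", mu_ms=mu_ms, sigma_ms=sigma_ms, tau_ms=tau_ms)

    @property
    def mean_ms(self) -> float:
        if self.kind == "constant":
            return self.value_ms
        return self.mu_ms + self.tau_ms


def draw_latency(model: LatencyModel, rng: np.random.Generator) -> float:
    """One non-negative latency sample, in ms."""
    if model.kind == "constant":
        return model.value_ms
    while True:
        x = rng.normal(model.mu_ms, model.sigma_ms) + rng.exponential(model.tau_ms)
        if x >= 0.0:
            return float(x)


@dataclass(frozen=True)
class RaceParameters:
    """Latency models for the GO1, GO2 and STOP processes.

    ``p_trigger_failure`` is the probability that the STOP process is never
    triggered on a redirect trial (so the GO1 saccade always escapes); it
    defaults to 0, the plain independent race.
    """

    go1: LatencyModel
    go2: LatencyModel
    stop: LatencyModel
    p_trigger_failure: float = 0.0
    p_corrective: float = 1.0

    def __post_init__(self) -> None:
        for p in (self.p_trigger_failure, self.p_corrective):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def default_race_parameters() -> RaceParameters:
    """Baseline synthetic-subject parameters.

    GO1 ~ exGaussian(250, 40, 70) gives a mean no-step latency of 320 ms,
    in the range typical of visually guided search saccades; GO2 is
    slightly faster; STOP is a constant 160 ms, a typical saccadic
    inhibition latency.  These are simulation fixtures, not empirical
    claims.
    """
    return RaceParameters(
        go1=LatencyModel.exgaussian(250.0, 40.0, 70.0),
        go2=LatencyModel.exgaussian(240.0, 40.0, 70.0),
        stop=LatencyModel.constant(160.0),
    )


@dataclass(frozen=True)
class TrialOutcome:
    """Simulated result of a single trial.

    ``rt_ms`` follows the task's reference conventions (array onset for
    no-step/noncompensated/follow, T2 onset for compensated).
    ``corrective_rt_ms`` — array-onset latency of the corrective saccade to
    T2 on noncompensated trials, or of the second saccade on follow trials.
    """

    trial: TrialSpec
    outcome: str
    rt_ms: float
    tsd_ms: Optional[float] = None
    corrective_rt_ms: Optional[float] = None

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.rt_ms < 0:
            raise ValueError("rt must be non-negative")

    @property
    def first_target(self) -> int:
        """Index of the target the first saccade goes to."""
        if self.outcome == "compensated":
            assert self.trial.t2_index is not None
            return self.trial.t2_index
        return self.trial.t1_index


def simulate_trial(params: RaceParameters, trial: TrialSpec,
                   tsd_ms: Optional[float], rng: np.random.Generator) -> TrialOutcome:
    """Run the race for one trial.

    On redirect trials the GO1 finishing time (from array onset) races the
    STOP finishing time ``tsd + stop``; GO1 winning produces a
    noncompensated trial whose saccade latency is the GO1 draw, STOP
    winning a compensated trial whose latency is a GO2 draw from T2 onset.
    """
    if (tsd_ms is not None) != (trial.trial_type == "redirect"):
        raise ValueError("tsd must be provided exactly on redirect trials")

    if trial.trial_type == "no_step":
        return TrialOutcome(trial=trial, outcome="no_step_saccade",
                            rt_ms=draw_latency(params.go1, rng))

    if trial.trial_type == "follow":
        rt = draw_latency(params.go1, rng)
        second = rt + draw_latency(params.go2, rng)
        return TrialOutcome(trial=trial, outcome="follow_saccade",
                            rt_ms=rt, corrective_rt_ms=second)

    go1 = draw_latency(params.go1, rng)
    triggered = rng.random() >= params.p_trigger_failure
    stop_finish = tsd_ms + draw_latency(params.stop, rng) if triggered else np.inf
    if go1 < stop_finish:
        corrective = None
        if rng.random() < params.p_corrective:
            corrective = tsd_ms + draw_latency(params.go2, rng)
            corrective = max(corrective, go1)  # cannot precede the T1 saccade
        return TrialOutcome(trial=trial, outcome="noncompensated", rt_ms=go1,
                            tsd_ms=tsd_ms, corrective_rt_ms=corrective)
    return TrialOutcome(trial=trial, outcome="compensated",
                        rt_ms=draw_latency(params.go2, rng), tsd_ms=tsd_ms)


@dataclass
class BehavioralDataset:
    """All trial outcomes of one simulated subject, in presentation order."""

    outcomes: list[TrialOutcome]
    subject: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for o in self.outcomes:
            t = o.trial
            rows.append({
                "subject": self.subject,
                "session": t.session,
                "trial_index": t.trial_index,
                "trial_type": t.trial_type,
                "tsd_ms": np.nan if o.tsd_ms is None else o.tsd_ms,
                "outcome": o.outcome,
                "rt_ms": o.rt_ms,
                "corrective_rt_ms": (np.nan if o.corrective_rt_ms is None
                                     else o.corrective_rt_ms),
                "t1_index": t.t1_index,
                "t2_index": -1 if t.t2_index is None else t.t2_index,
                "fixation_ms": t.fixation_ms,
            })
        return pd.DataFrame(rows)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "BehavioralDataset":
        df = pd.read_csv(path, sep="\t")
        outcomes = []
        for row in df.itertuples():
            trial = TrialSpec(
                trial_type=row.trial_type,
                t1_index=int(row.t1_index),
                t2_index=None if int(row.t2_index) < 0 else int(row.t2_index),
                fixation_ms=float(row.fixation_ms),
                session=int(row.session),
                trial_index=int(row.trial_index),
            )
            outcomes.append(TrialOutcome(
                trial=trial,
                outcome=row.outcome,
                rt_ms=float(row.rt_ms),
                tsd_ms=None if pd.isna(row.tsd_ms) else float(row.tsd_ms),
                corrective_rt_ms=(None if pd.isna(row.corrective_rt_ms)
                                  else float(row.corrective_rt_ms)),
            ))
        subject = int(df["subject"].iloc[0]) if len(df) else 0
        return cls(outcomes=outcomes, subject=subject)


def simulate_subject(params: RaceParameters, plan: Sequence[SessionPlan],
                     staircase0: StaircaseState, rng: np.random.Generator,
                     subject: int = 0) -> BehavioralDataset:
    """Simulate one subject through an experiment plan.

    Redirect trials consume the current staircase TSD and feed the race
    outcome back into the one-up/one-down rule, so over a session the TSD
    tracks the delay at which inhibition succeeds half the time.
    """
    if not plan or not any(s.trials for s in plan):
        raise ValueError("experiment plan is empty")
    state = staircase0
    outcomes: list[TrialOutcome] = []
    for session in plan:
        for trial in session.trials:
            if trial.trial_type == "redirect":
                out = simulate_trial(params, trial, state.tsd_ms, rng)
                state = staircase_update(state, out.outcome)
            else:
                out = simulate_trial(params, trial, None, rng)
            outcomes.append(out)
    return BehavioralDataset(outcomes=outcomes, subject=subject)


def inhibition_function(params: RaceParameters, tsd_grid_ms: Sequence[float],
                        n_reps: int, rng: np.random.Generator,
                        trial: TrialSpec | None = None) -> np.ndarray:
    """P(noncompensated) at each fixed TSD, by Monte Carlo.

    Inhibiting the saccade to T1 gets harder as the step comes later, so
    the curve rises with TSD (exactly a step function when both latencies
    are constants).
    """
    if len(tsd_grid_ms) == 0:
        raise ValueError("tsd grid is empty")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if trial is None:
        trial = TrialSpec(trial_type="redirect", t1_index=0, t2_index=4,
                          fixation_ms=1500.0, session=0, trial_index=0)
    probs = np.empty(len(tsd_grid_ms))
    for i, tsd in enumerate(tsd_grid_ms):
        n_nc = sum(
            simulate_trial(params, trial, float(tsd), rng).outcome == "noncompensated"
            for _ in range(n_reps)
        )
        probs[i] = n_nc / n_reps
    return probs
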