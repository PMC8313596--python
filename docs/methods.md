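# Methods

## The race model and its assumptions

Redirect-trial behavior is generated by an independent race between a GO₁
process (latency to launch the saccade to T1, measured from array onset) and
a STOP process triggered by the target step (latency measured from T2 onset).
The saccade to T1 is executed iff `GO1 < TSD + STOP`; otherwise gaze goes
directly to T2 with an independent GO₂ latency, reported relative to T2
onset. Independence is assumed both stochastically (no correlation between
GO and STOP finishing times) and contextually (the GO distribution on
redirect trials equals the no-step distribution) — the standard assumptions
under which the integration method is consistent. A trigger-failure
probability (STOP never starts) is available but defaults to 0, keeping the
baseline model the plain independent race.

Latencies are constants or ex-Gaussians (Gaussian(μ, σ) ⊛ Exponential(τ),
mean μ + τ), the conventional descriptive RT family; draws are truncated at
zero by resampling.

## Task and staircase parameters

| parameter | default | notes |
|---|---|---|
| array positions | 8, evenly spaced | circular array |
| eccentricity | 9° | all elements equidistant from fixation |
| element size | 0.7° | metadata only; not rendered |
| trial mix | 30% no-step / 40% redirect / 30% follow | largest-remainder allocation makes 4×60 trials give exactly 72/96/72 |
| fixation period | uniform 1000–2000 ms | per trial |
| trial duration | 4 s | 240 samples at 60 Hz |
| rest blocks | 6 × 10 s per session | evenly spaced insertion points |
| T1–T2 separation | ≥ 90° polar angle | discourages averaging saccades |
| TSD staircase | start 100 ms, step 67 ms | stored as integer display frames (6 and 4 at 60 Hz) so every TSD is a frame multiple; floor 1 frame, no ceiling |

The staircase is one-up/one-down on classified redirect outcomes:
compensated → TSD + step, noncompensated → TSD − step (clamped),
indeterminate → unchanged. A 0-frame floor would be degenerate (the target
would never appear at T1), hence the 1-frame minimum. Fractional per-type
trial counts are resolved by largest-remainder apportionment over the whole
experiment with positional tie-break, which is deterministic given the
configuration and independent of the RNG seed.

## Simulator defaults

GO₁ ~ exGaussian(250, 40, 70) ms (mean 320 ms), GO₂ ~ exGaussian(240, 40,
70) ms, STOP = 160 ms constant. These are fixtures chosen to place simulated
no-step RTs in the low-320 ms range and TSRT near 160 ms — values typical of
healthy adults on saccadic countermanding tasks — not empirical claims. The
pipeline's two synthetic groups differ only in STOP latency (160 vs 170 ms),
emulating slower inhibition in a clinical group. Corrective saccades on
noncompensated trials are always generated (configurable), with array-onset
latency `TSD + GO₂`, clamped to not precede the T1 saccade.

At staircase equilibrium `P(GO1 < TSD + STOP) = 0.5`, so the long-run mean
TSD tracks `median(GO1) − STOP` (the median, not the mean — the distinction
matters for the skewed ex-Gaussian). Tests oracle this with
`scipy.stats.exponnorm`.

## Gaze synthesis

Traces are 4 s at 60 Hz. Saccades follow a logistic position ramp with
main-sequence duration `2.2 ms/° × amplitude + 21 ms`, exactly constant
outside the ramp so inter-saccadic velocity is identically zero on clean
renders. The noise model adds isotropic Gaussian position noise (default sd
0.15°), a constant calibration drift offset, and Poisson-count blinks
rendered as invalid samples held at the last valid position (an optional
excursion mode produces large artifacts instead). What the generator does
*not* emulate: microsaccades, smooth pursuit, pupil-size coupling,
position-dependent camera noise, or the temporally correlated noise of real
video eye trackers. Detector round-trip results on synthetic traces
therefore demonstrate internal consistency of the pipeline, not performance
on real recordings.

## Detection pipeline

- **Drift correction** subtracts the mean valid eye position in a ±50 ms
  window around array onset; with no valid sample in the window the trace is
  returned uncorrected with a warning. Idempotent on offset-only traces.
- **Velocity** is the central-difference derivative of position, each
  component filtered forward-backward (zero-phase, preserving onset timing)
  with a 5th-order Butterworth low-pass. The nominal 40 Hz cutoff exceeds
  the 30 Hz Nyquist limit of 60 Hz data, so the effective cutoff is clamped
  to 0.9 × Nyquist with a warning; higher-rate data honor 40 Hz literally.
- **Events** are maximal runs of speed > 30°/s (a liberal threshold,
  configurable) of at least 2 samples, merged across gaps < 20 ms.
  Invalid spans ≤ 100 ms are linearly interpolated; longer spans are masked
  and any event overlapping them is dropped — a deterministic stand-in for
  manual artifact review.
- **Online classification** of redirect trials: the first run of ≥ 2 valid
  samples outside a 2° fixation window, later than 100 ms after array onset,
  is assigned to T1 or T2 if its mean direction lies within 45° of the
  fixation→target vector (ties to T2, which requires the larger excursion);
  otherwise the trial is indeterminate. The 100 ms floor is referenced to
  array onset, consistent with the anticipation-exclusion rule; a
  step-onset-referenced variant would be a one-line config change.
- **RT extraction**: first event onset after array onset, minus array onset
  (no-step, noncompensated, follow) or minus T2 onset (compensated); onsets
  earlier than 100 ms after array onset are flagged as anticipations and
  excluded.

## TSRT and summaries

The integration estimate uses the 1-based nearest-rank quantile
`ceil(p × n)` by default (linear interpolation available); the quantile
convention is not canonical in the literature, so it is exposed as an
option. `p_noncompensated` is computed over determinate redirect trials by
default, mirroring the online rule that indeterminate trials leave the
staircase unchanged; a denominator over all redirect trials is available.
TSRT is computed on trials pooled across sessions. Vincentized distributions
sort each subject's RTs into 10 equal-count bins (remainder trials assigned
to the earliest bins — any fixed rule works; this one is documented), then
average bin means across subjects with their standard errors.

## Group statistics

- TSRT group comparison: pooled-variance independent t-test, one-tailed in
  the direction of the stated hypothesis (df = n₁ + n₂ − 2).
- Condition RTs: two-way mixed ANOVA (trial type within, group between),
  computed from sums of squares with weighted marginal means and the
  interaction obtained by subtraction, which matches pingouin's mixed-model
  decomposition exactly (verified in tests). Greenhouse–Geisser ε comes from
  the double-centered covariance of condition scores; corrected dfs are
  ε-scaled and the corrected p uses the mixed-design F at those dfs (the
  SPSS convention). Effect sizes are classical η² = SS_effect / SS_total.
- Covariates: Spearman rank correlation with midrank ties (scipy).
- No multiple-testing correction is applied to the behavioral tests.

## Determinism

All randomness flows from one integer seed. The pipeline derives per-subject
substreams via `numpy.random.SeedSequence(seed, spawn_key=(1, subject))`,
with separate children for plan construction, behavior and rendering, so
adding subjects or switching modes never perturbs earlier subjects' data.
Identical config + seed reproduce byte-identical output tables.

## Problem sizes

The test suite and acceptance script use 100 replicate subjects for the
staircase-calibration check, 200 subjects per STOP latency for parameter
recovery, 3000–4000 Monte-Carlo repetitions per TSD for inhibition-function
estimates, and 2-session renders for detector round-trips — sizes at which
the Monte-Carlo error is comfortably below the assertion tolerances while
the full suite runs in well under a minute.

## Known limitations

- The detector's onset resolution is one 60 Hz sample (16.7 ms); RT-level
  assertions are set accordingly.
- The integration method shows the expected small finite-sample bias
  (a few ms low with 72 no-step trials per subject); recovery tolerances
  reflect it rather than hide it.
- Follow trials are simulated and rendered but not analyzed, matching the
  task's role for them.
- Real-data ingestion is supported only insofar as recordings are provided
  in the package's trace/manifest layout; no vendor formats are parsed.
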