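"""Simulate one subject's behavior with the independent race model.

The GO1 process (ex-Gaussian, mean 320 ms) races a constant-160 ms STOP
process on each redirect trial; the one-up/one-down staircase moves the
target-step delay (TSD) 67 ms after every classified redirect trial, so
inhibition succeeds on roughly half of them.
"""

import numpy as np

from sacstep import (ArrayGeometry, StaircaseState, build_experiment_plan,
                     default_race_parameters, simulate_subject)

rng = np.random.default_rng(2)
geometry = ArrayGeometry()
plan = build_experiment_plan(4, 60, (0.30, 0.40, 0.30), geometry, rng)
dataset = simulate_subject(default_race_parameters(), plan,
                           StaircaseState.from_ms(100.0), rng)

df = dataset.to_frame()
redirect = df[df.trial_type == "redirect"]
p_comp = (redirect.outcome == "compensated").mean()
print(f"redirect trials: {len(redirect)}, "
      f"compensated: {100 * p_comp:.1f}%  (staircase targets 50%)")
print(f"mean TSD: {redirect.tsd_ms.mean():.0f} ms")
for cond, label in (("no_step_saccade", "no-step"),
                    ("compensated", "compensated"),
                    ("noncompensated", "noncompensated")):
    rts = df.loc[df.outcome == cond, "rt_ms"]
    print(f"mean {label:15s} RT: {rts.mean():6.1f} ms  (n={len(rts)})")
# Noncompensated saccades are faster than no-step saccades because the
# race lets only fast GO finishes escape inhibition.
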