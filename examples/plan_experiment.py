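"""Build a randomized search-step experiment plan and inspect its design.

The standard design is four 5-minute sessions of 60 trials, interleaving
no-step (30%), redirect (40%) and follow (30%) trials, with six 10 s rest
blocks per session and T1-T2 separations of at least 90 degrees.
"""

from collections import Counter

import numpy as np

from sacstep import ArrayGeometry, build_experiment_plan

geometry = ArrayGeometry()          # 8 positions, 9 deg eccentricity
rng = np.random.default_rng(1)
plans = build_experiment_plan(4, 60, (0.30, 0.40, 0.30), geometry, rng)

counts = Counter(t.trial_type for p in plans for t in p.trials)
print("trial counts over the experiment:", dict(counts))

separations = [geometry.angular_separation_deg(t.t1_index, t.t2_index)
               for p in plans for t in p.trials if t.t2_index is not None]
print(f"minimum T1-T2 separation: {min(separations):.0f} deg")
print("rest blocks in session 0:", plans[0].rest_blocks)
print("first three trials:")
for t in plans[0].trials[:3]:
    print(f"  {t.trial_type:9s} t1={t.t1_index} t2={t.t2_index} "
          f"fixation={t.fixation_ms:.0f} ms")
# The counts are exact (largest-remainder allocation), the order random,
# and every stepped trial respects the 90-degree separation constraint.
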