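"""Classify per-epoch activity levels from raw 100 Hz acceleration.

The jerk-proportional metric (moving SD of the acceleration magnitude,
window 5, averaged over 10-s blocks) cancels gravity and separates
dwelling, level walking and stair climbing; 3-means turns it into
low/middle/high labels.
"""

import numpy as np

from beaconloc import (
    accel_magnitude,
    classify_levels,
    jerk_metric,
    load_example_map,
    simulate_trial,
    trial_config,
)

beacons, _, graph = load_example_map()
trial = simulate_trial(graph, beacons, trial_config(1, seed=42))

mag = accel_magnitude(trial.accel["ax"], trial.accel["ay"], trial.accel["az"])
metric = jerk_metric(mag)
levels = np.array(classify_levels(metric, seed=0))
moving = trial.truth.moving[: len(levels)]

print(f"{len(metric)} epochs; metric range "
      f"{metric.min():.4f}-{metric.max():.4f} g")
for level in ("low", "middle", "high"):
    n = int((levels == level).sum())
    frac_moving = float(np.mean(moving[levels == level])) if n else 0.0
    print(f"  {level:<6} {n:3d} epochs, {frac_moving:4.0%} of them while moving")
print("dwelling epochs labelled low:",
      f"{np.mean(levels[~moving] == 'low'):.0%}",
      "- the highest activity occurs between rooms, not inside them")
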