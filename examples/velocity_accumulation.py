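"""The leaky-integrator velocity estimate and its tapping-error predictions.

Shows how slowly a 2%-per-frame update tracks a velocity change, and how the
carry-over of the estimate across trials predicts that the previous trial's
target velocity biases where the current tap lands.
"""

import numpy as np

import interceptsim as isim
from interceptsim.accumulation import accumulate, half_life_steps

# tracking an abrupt change: 0 -> 600 mm/s
n = half_life_steps(0.02)
series = accumulate(np.full(60, 600.0), 0.02, 0.0)
print(f"half-life of the estimate: {n} frames = {n / 120 * 1000:.0f} ms "
      "(almost 300 ms to get halfway to a new velocity)")
print(f"after a 0.5 s trial the estimate has only reached {series[-1]:.0f} mm/s")

# predicted influence of the previous trial's mean velocity (about 1.2 mm)
diffs = isim.previous_trial_influence(n_sessions=40, n_trials=500, seed=0)
print(f"previous-trial mean-velocity split: {diffs['mean_velocity']:.2f} mm "
      "difference in predicted tapping error")
print(f"same split on the last 200 ms of the previous trial: "
      f"{diffs['last200_velocity']:.2f} mm")
# both are nonzero only because the estimate carries across trials
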