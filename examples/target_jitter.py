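"""Generate the lateral target motion of the tapping experiments.

Builds a random-walk jitter trial (stationary target), a drifting-jitter
trial (target moving rightward at 60 cm/s on average) and one of the eight
constant-acceleration trajectories, and prints their key kinematic numbers.
"""

import numpy as np

import interceptsim as isim

# stationary target with +/-1.67 mm jitter steps at 120 Hz
walk = isim.make_random_walk(61, seed=1)
print("random walk: per-frame speed "
      f"{abs(walk.step_velocities[0]) / 10:.0f} cm/s, "
      f"final position {walk.positions[-1]:+.2f} mm after 0.5 s")
# each step is only 1/6 of the target radius, but corresponds to 20 cm/s

scheme = isim.variability_scheme("standard")
drift = isim.make_drifting_walk(61, scheme.step_options, seed=1, start_position=-200.0)
print(f"drifting walk: mean velocity {drift.step_velocities.mean() / 10:.1f} cm/s "
      f"(scheme mean {scheme.mean_velocity / 10:.0f} cm/s), "
      f"travelled {drift.positions[-1] - drift.positions[0]:.0f} mm")
# the 40/80 cm/s steps make the jitter nearly invisible on top of the drift

spec = isim.AccelTrajectorySpec(direction=1, acceleration=400.0, speed_class="slow")
accel = isim.make_accel_trajectory(spec, n_frames=120)
v0 = isim.solve_initial_speed(spec)
frame_700 = round(0.7 / (1 / 120))
print(f"accelerating target: initial speed {v0 / 10:.1f} cm/s, "
      f"position at 700 ms {accel.positions[frame_700]:+.0f} mm "
      "(300 mm past centre by design)")

# a full 168-trial session: 9 reference blocks alternating with 8 grouped ones
blocks = isim.make_session_blocks(7)
kinds = [b.block_kind for b in blocks]
print(f"session: {len(blocks)} blocks, {sum(b.n_trials for b in blocks)} trials; "
      f"{kinds.count('reference')} reference blocks")
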