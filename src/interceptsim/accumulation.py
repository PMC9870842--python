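"""Delayed-extrapolation aiming with a leaky-integrator velocity estimate.

The aiming model assumes that at time ``t`` the hand is guided toward the
target position seen one visuomotor delay δ earlier, extrapolated to the
anticipated tap time with a velocity estimate ``v``:

    A_t = T_{t-δ} + v_{t-δ} * (t_tap - (t - δ))

so the predicted tapping error (aim point at the tap minus target at the tap)
is

    A_tap - T_tap = T_{tap-δ} - T_tap + v_{tap-δ} * δ.

The velocity estimate is a leaky integrator updated once per displayed frame:

    v_s = (1 - w) * v_{s-1} + w * v_step

with w = 0.02 per 120 Hz frame by default (a fast variant uses w = 0.15), and
the estimate carries across trials: each trial starts from the previous
trial's final value.  δ is 100 ms, i.e. exactly 12 frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .errors import InvalidSpecError
from .targets import FRAME_DT, TargetTrajectory

#: default and fast per-frame update weights
DEFAULT_WEIGHT = 0.02
FAST_WEIGHT = 0.15

#: visuomotor delay: 100 ms = 12 frames at 120 Hz
DELAY_FRAMES = 12


@dataclass(frozen=True)
class AccumulatorParams:
    """Leaky-integrator parameters: per-frame update weight and delay."""

    weight: float = DEFAULT_WEIGHT
    delay_frames: int = DELAY_FRAMES
    frame_interval: float = FRAME_DT

    def __post_init__(self) -> None:
        if not 0.0 < self.weight <= 1.0:
            raise InvalidSpecError("weight must be in (0, 1]")
        if self.delay_frames < 0:
            raise InvalidSpecError("delay_frames must be nonnegative")

    @property
    def delay_s(self) -> float:
        return self.delay_frames * self.frame_interval


def update_velocity(v_prev: float, v_step: float, w: float = DEFAULT_WEIGHT) -> float:
    """One leaky-integrator update: ``(1 - w) * v_prev + w * v_step``."""
    if not 0.0 < w <= 1.0:
        raise InvalidSpecError("w must be in (0, 1]")
    return (1.0 - w) * v_prev + w * v_step


def accumulate(step_velocities: np.ndarray, w: float, initial_v: float) -> np.ndarray:
    """Velocity-estimate series for a sequence of displayed step velocities.

    Returns an array of length ``len(step_velocities) + 1`` whose entry ``s``
    is the estimate after the first ``s`` steps (entry 0 is ``initial_v``).
    """
    if not 0.0 < w <= 1.0:
        raise InvalidSpecError("w must be in (0, 1]")
    u = np.asarray(step_velocities, dtype=float)
    if len(u) == 0:
        return np.array([initial_v])
    zi = np.array([(1.0 - w) * initial_v])
    filtered, _ = lfilter([w], [1.0, -(1.0 - w)], u, zi=zi)
    return np.concatenate(([initial_v], filtered))


def geometric_estimate(initial_v: float, v_const: float, w: float, n_steps: int) -> float:
    """Closed form of ``accumulate`` for a constant input:
    ``v_const + (initial_v - v_const) * (1 - w)**n``."""
    return v_const + (initial_v - v_const) * (1.0 - w) ** n_steps


def half_life_steps(w: float = DEFAULT_WEIGHT) -> int:
    """Number of updates needed to move at least halfway to a new constant
    value after an abrupt change: ``ceil(ln 0.5 / ln(1 - w))``."""
    if not 0.0 < w < 1.0:
        raise InvalidSpecError("w must be in (0, 1)")
    return math.ceil(math.log(0.5) / math.log(1.0 - w))


def aim_point(T_delayed: float, v_delayed: float, t: float, t_tap: float, delta: float) -> float:
    """Extrapolated aim point ``T_{t-δ} + v_{t-δ} * (t_tap - (t - δ))``."""
    if t_tap < t - delta:
        raise InvalidSpecError("t_tap must not precede the delayed sample time")
    return T_delayed + v_delayed * (t_tap - (t - delta))


def predicted_tap_error(
    traj: TargetTrajectory,
    tap_frame: int,
    v_estimate_at_delay: float,
    delay_frames: int = DELAY_FRAMES,
) -> float:
    """Predicted signed tapping error ``T_{tap-δ} - T_tap + v_{tap-δ} * δ``
    (positive = tap beyond the target in the rightward-positive convention)."""
    if tap_frame >= traj.n_frames:
        raise InvalidSpecError("tap_frame outside the trajectory")
    if tap_frame < delay_frames:
        raise InvalidSpecError(
            "tap earlier than the visuomotor delay after trajectory onset: "
            "the delayed target sample is undefined"
        )
    delta = delay_frames * FRAME_DT
    return float(
        traj.positions[tap_frame - delay_frames]
        - traj.positions[tap_frame]
        + v_estimate_at_delay * delta
    )


@dataclass(frozen=True)
class TrialAccumulation:
    """Result of running the accumulator over one trial."""

    estimates: np.ndarray  # per-frame series; entry s = estimate after s steps
    predicted_error: float  # mm
    final_v: float  # mm/s, carried over to the next trial


def run_trial_accumulation(
    traj: TargetTrajectory,
    tap_frame: int,
    params: AccumulatorParams = AccumulatorParams(),
    initial_v: float = 0.0,
) -> TrialAccumulation:
    """Run the leaky integrator over the steps displayed up to the tap and
    evaluate the predicted tapping error with the estimate held at tap − δ.

    The estimate is updated once per displayed frame (the target is visible
    from its appearance until the tap), and the final value is returned for
    carry-over to the next trial.
    """
    if tap_frame > traj.n_frames - 1:
        raise InvalidSpecError("tap_frame outside the trajectory")
    estimates = accumulate(traj.step_velocities[:tap_frame], params.weight, initial_v)
    v_delayed = float(estimates[tap_frame - params.delay_frames])
    error = predicted_tap_error(traj, tap_frame, v_delayed, params.delay_frames)
    return TrialAccumulation(estimates, error, float(estimates[-1]))
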