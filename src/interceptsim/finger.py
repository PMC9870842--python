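"""Synthetic 500 Hz finger trajectories responding to target steps.

Two response models describe how the finger corrects for a lateral target
displacement D once the response starts (100 ms after the step), with T the
time remaining until the tap:

* minimum jerk — the smoothest correction that traverses D in T, with
  velocity profile ``xdot = 30 D u^2 (1-u)^2 / T`` (u = time as a fraction
  of T);
* mass–spring–damper — ``xddot + b xdot + k x = 0`` with b = 75 1/s and a
  stiffness that grows for later steps, ``k = 3800 - 16 T[ms] 1/s^2``; x is
  the remaining discrepancy (x(0) = D, xdot(0) = 0) and the response
  velocity toward the target is −xdot.  The system is underdamped (the
  correction overshoots) when ``b^2 < 4 k(T)``, i.e. for T below about
  150 ms.

``synthesize_trial`` superposes one response per target step (each step is an
independent pull on the finger) on top of a stereotyped point-to-point
transport movement, producing ground-truth data for the analysis pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidSpecError
from .targets import FRAME_DT, TargetTrajectory

#: motion-capture sample interval (500 Hz)
SAMPLE_DT = 0.002

#: response latency to a target step
DEFAULT_LATENCY = 0.1

#: mass-spring-damper constants
MSD_DAMPING = 75.0  # 1/s
MSD_K_INTERCEPT = 3800.0  # 1/s^2
MSD_K_SLOPE = 16.0  # 1/s^2 per ms of available time


@dataclass(frozen=True)
class MinJerkSpec:
    """A displacement D (mm) to be traversed in available time T (s)."""

    D: float
    T: float

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise InvalidSpecError("available time T must be positive")


@dataclass(frozen=True)
class MSDSpec:
    """Mass-spring-damper response parameters for one step."""

    D: float
    T_ms: float
    b: float = MSD_DAMPING
    k_intercept: float = MSD_K_INTERCEPT
    k_slope: float = MSD_K_SLOPE

    @property
    def k(self) -> float:
        return self.k_intercept - self.k_slope * self.T_ms

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise InvalidSpecError("stiffness k(T) must be positive")


def min_jerk_velocity(D: float, T: float, t_frac) -> np.ndarray | float:
    """Minimum-jerk correction velocity ``30 D u^2 (1-u)^2 / T`` (mm/s for D
    in mm and T in s); zero at both ends, peaking at ``1.875 D / T``."""
    if T <= 0:
        raise InvalidSpecError("available time T must be positive")
    u = np.asarray(t_frac, dtype=float)
    out = 30.0 * D * u**2 * (1.0 - u) ** 2 / T
    return out if out.ndim else float(out)


def min_jerk_displacement(D: float, t_frac) -> np.ndarray | float:
    """Integral of the minimum-jerk velocity: ``D (10u^3 - 15u^4 + 6u^5)``."""
    u = np.clip(np.asarray(t_frac, dtype=float), 0.0, 1.0)
    out = D * (10.0 * u**3 - 15.0 * u**4 + 6.0 * u**5)
    return out if out.ndim else float(out)


def critical_time_ms(
    b: float = MSD_DAMPING, k_intercept: float = MSD_K_INTERCEPT, k_slope: float = MSD_K_SLOPE
) -> float:
    """Available time T* at which ``b^2 = 4 k(T)``: responses to steps with
    less time than this are underdamped (about 149.6 ms)."""
    return (k_intercept - b**2 / 4.0) / k_slope


def msd_position(spec: MSDSpec, t) -> np.ndarray:
    """Closed-form remaining discrepancy x(t) with x(0)=D, xdot(0)=0."""
    t = np.asarray(t, dtype=float)
    b, k, D = spec.b, spec.k, spec.D
    disc = b * b - 4.0 * k
    if abs(disc) < 1e-9:  # critically damped
        r = -b / 2.0
        return D * np.exp(r * t) * (1.0 - r * t)
    if disc > 0:  # overdamped
        s = np.sqrt(disc)
        l1, l2 = (-b + s) / 2.0, (-b - s) / 2.0
        return D * (l2 * np.exp(l1 * t) - l1 * np.exp(l2 * t)) / (l2 - l1)
    w = np.sqrt(-disc) / 2.0  # underdamped
    return D * np.exp(-b * t / 2.0) * (np.cos(w * t) + (b / (2.0 * w)) * np.sin(w * t))


def msd_velocity(spec: MSDSpec, t) -> np.ndarray:
    """Closed-form response velocity toward the target, −xdot(t)."""
    t = np.asarray(t, dtype=float)
    b, k, D = spec.b, spec.k, spec.D
    disc = b * b - 4.0 * k
    if abs(disc) < 1e-9:
        r = -b / 2.0
        return -D * (r * np.exp(r * t) * (1.0 - r * t) - r * np.exp(r * t))
    if disc > 0:
        s = np.sqrt(disc)
        l1, l2 = (-b + s) / 2.0, (-b - s) / 2.0
        return -D * l1 * l2 * (np.exp(l1 * t) - np.exp(l2 * t)) / (l2 - l1)
    w = np.sqrt(-disc) / 2.0
    # xdot = -D (b^2/(4w) + w) e^{-bt/2} sin(wt)
    return D * (b * b / (4.0 * w) + w) * np.exp(-b * t / 2.0) * np.sin(w * t)


def msd_response(spec: MSDSpec, duration: float, dt: float = SAMPLE_DT):
    """Sampled response-velocity profile (times, −xdot) over ``duration``."""
    t = np.arange(0.0, duration + dt / 2, dt)
    return t, msd_velocity(spec, t)


@dataclass(frozen=True)
class FingerTrajectory:
    """500 Hz finger samples for one trial, aligned to target onset at t=0.

    x is lateral (mm, rightward positive), y along the screen toward the
    target, z the distance from the screen; the tap is annotated by index.
    """

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    tap_index: int
    meta: dict = field(default_factory=dict)

    @property
    def tap_time(self) -> float:
        return float(self.times[self.tap_index])

    @property
    def sample_interval(self) -> float:
        return float(self.times[1] - self.times[0])


#: the linear stiffness law is characterized for short available times and
#: crosses zero near T = 237 ms; responses to steps with more time available
#: use the stiffness frozen at this value (the response itself still runs for
#: the full available time)
MSD_STIFFNESS_CLAMP_MS = 150.0


def _step_response_displacement(model: str, D: float, T: float, t: np.ndarray) -> np.ndarray:
    """Displacement toward the new target position at times t since response
    onset (zero before onset)."""
    out = np.zeros_like(t)
    active = t > 0
    if model == "min_jerk":
        out[active] = min_jerk_displacement(D, t[active] / T)
    elif model == "msd":
        spec = MSDSpec(D, min(T * 1000.0, MSD_STIFFNESS_CLAMP_MS))
        out[active] = D - msd_position(spec, t[active])
    else:
        raise InvalidSpecError(f"unknown response model {model!r}")
    return out


def synthesize_trial(
    traj: TargetTrajectory,
    tap_frame: int,
    model: str = "msd",
    latency: float = DEFAULT_LATENCY,
    reaction_time: float = 0.21,
    noise_sd: float = 0.5,
    seed: int | np.random.Generator = 0,
    reach_amplitude: float = 250.0,
    lift_height: float = 40.0,
    mean_step: float | None = None,
    gentle_landing: bool = False,
) -> FingerTrajectory:
    """Synthesize one finger trajectory responding to a jittering target.

    The lateral component is a minimum-jerk transport from the start to the
    target's expected (mean-velocity) position at the tap, plus one response
    model evaluation per target step (input = that step's deviation from the
    scheme's mean step, each with its own remaining time T), plus optional
    white positional noise.  The y/z components are a stereotyped reach of
    ``reach_amplitude`` ending in a detectable impact (unless
    ``gentle_landing``, which lands with zero approach velocity so that tap
    detection must fall back to the height minimum).
    """
    if tap_frame < 1 or tap_frame > traj.n_frames - 1:
        raise InvalidSpecError("tap_frame outside the trajectory")
    t_tap = tap_frame * FRAME_DT
    if t_tap <= reaction_time:
        raise InvalidSpecError("tap before movement onset")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n_after = 5  # samples kept after the impact
    times = np.arange(0.0, t_tap + (n_after + 0.5) * SAMPLE_DT, SAMPLE_DT)
    tap_index = int(round(t_tap / SAMPLE_DT))
    mt = t_tap - reaction_time
    phase = np.clip((times - reaction_time) / mt, 0.0, 1.0)

    steps = traj.step_sizes[:tap_frame]
    mean_step_value = float(steps.mean()) if mean_step is None else mean_step
    expected_tap_pos = traj.positions[0] + mean_step_value * tap_frame
    x = traj.positions[0] + min_jerk_displacement(expected_tap_pos - traj.positions[0], phase)

    for k, step in enumerate(steps):
        D = step - mean_step_value
        if D == 0.0:
            continue
        onset = (k + 1) * FRAME_DT + latency  # step k lands at frame k+1
        T = t_tap - onset
        if T <= SAMPLE_DT:
            continue
        x = x + _step_response_displacement(model, D, T, times - onset)

    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=len(times))

    y = min_jerk_displacement(reach_amplitude, phase)
    if gentle_landing:
        z = lift_height * np.sin(np.pi * phase) ** 2
    else:
        z = lift_height * np.sin(np.pi * phase**0.8)
    z = np.where(times > t_tap, 0.0, np.maximum(z, 0.0))

    return FingerTrajectory(
        times, x, y, z, tap_index,
        meta=dict(model=model, latency=latency, reaction_time=reaction_time,
                  tap_frame=tap_frame, gentle_landing=gentle_landing),
    )
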