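"""Trial-to-trial error correction with forgetting.

Across trials the aim point is adjusted by a spatial offset ``C_s`` (mm) and a
temporal offset ``C_t`` (s) that extends the extrapolation horizon:

    A_{t,i} = T_{t-δ} + v_{t-δ} * (t_tap + C_t - (t - δ)) + C_s

After each tap both corrections decay to 95% of their value (forgetting) and
are adjusted against the observed errors:

    C_s(i+1) = 0.95 * C_s(i) - 0.25 * (A_tap - T_tap)
    C_t(i+1) = 0.95 * C_t(i) - 0.15 * (t_passed - t_tap)

where ``t_passed`` is when the target passed (or would have passed) the tapped
position.  The retention factor below 1 is what keeps the two corrections from
drifting off together when both can compensate the same error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidSpecError
from .targets import TargetTrajectory


@dataclass(frozen=True)
class CorrectionState:
    """Current spatial (mm) and temporal (s) aim corrections."""

    c_s: float = 0.0
    c_t: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.c_s) and np.isfinite(self.c_t)):
            raise InvalidSpecError("corrections must be finite")


@dataclass(frozen=True)
class LearningParams:
    retention: float = 0.95
    spatial_rate: float = 0.25
    temporal_rate: float = 0.15

    def __post_init__(self) -> None:
        for name in ("retention", "spatial_rate", "temporal_rate"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise InvalidSpecError(f"{name} must be in (0, 1]")


def corrected_aim_point(
    T_delayed: float,
    v_delayed: float,
    t: float,
    t_tap: float,
    delta: float,
    state: CorrectionState,
) -> float:
    """Aim point with the learned corrections applied: the extrapolation
    horizon is extended by ``C_t`` and the result offset by ``C_s``."""
    if t_tap < t - delta:
        raise InvalidSpecError("t_tap must not precede the delayed sample time")
    return T_delayed + v_delayed * (t_tap + state.c_t - (t - delta)) + state.c_s


def update_spatial(
    state: CorrectionState, tap_error: float, params: LearningParams = LearningParams()
) -> CorrectionState:
    """Retention then compensation of a fraction of the signed tapping error."""
    return CorrectionState(
        c_s=params.retention * state.c_s - params.spatial_rate * tap_error,
        c_t=state.c_t,
    )


def update_temporal(
    state: CorrectionState, timing_error: float, params: LearningParams = LearningParams()
) -> CorrectionState:
    """Retention then compensation of a fraction of ``t_passed - t_tap``."""
    if not np.isfinite(timing_error):
        raise InvalidSpecError("timing_error must be finite")
    return CorrectionState(
        c_s=state.c_s,
        c_t=params.retention * state.c_t - params.temporal_rate * timing_error,
    )


@dataclass(frozen=True)
class TimingError:
    """``t_passed - t_tap`` and whether the crossing had to fall back to the
    time of closest approach (tapped position never reached)."""

    value: float
    undefined_crossing: bool = False


def timing_error(
    traj: TargetTrajectory, tapped_position: float, t_tap: float
) -> TimingError:
    """Signed time between when the target passed (or, by linear extrapolation
    beyond the sampled trajectory, would have passed) the tapped position and
    the tap.

    Requires the trajectory to move monotonically; if the tapped position is
    never reached and the extrapolation cannot reach it either (motion away
    from it), the signed time of closest approach is returned with the
    ``undefined_crossing`` flag set.
    """
    pos = traj.positions
    times = traj.frame_times
    if len(pos) < 2:
        raise InvalidSpecError("need at least two frames to invert the motion")
    direction = np.sign(traj.step_velocities[0]) or np.sign(pos[-1] - pos[0])
    if direction == 0:
        raise InvalidSpecError("trajectory does not move; crossing undefined")
    p = pos * direction
    x = tapped_position * direction
    if x <= p[0]:
        # before the first sample: extrapolate backwards at the first velocity
        t_passed = times[0] - (p[0] - x) / abs(traj.step_velocities[0])
        return TimingError(float(t_passed - t_tap))
    crossed = np.nonzero(p >= x)[0]
    if len(crossed):
        i = int(crossed[0])  # first crossing, robust to later reversals
        t_passed = times[i - 1] + (x - p[i - 1]) / (p[i] - p[i - 1]) * (times[i] - times[i - 1])
        return TimingError(float(t_passed - t_tap))
    v_end = traj.step_velocities[-1] * direction
    if v_end <= 0:  # stopped or reversed short of the tapped position
        i = int(np.argmax(p))
        return TimingError(float(times[i] - t_tap), undefined_crossing=True)
    t_passed = times[-1] + (x - p[-1]) / v_end
    return TimingError(float(t_passed - t_tap))
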