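"""Kinematic analysis of tapping trials.

Implements the step-triggered analysis pipeline: Savitzky–Golay smoothing of
the 500 Hz finger data (second-order polynomial over 9 samples, value and
derivative at the window centre), tap detection from the impact deceleration,
trial exclusion/interpolation rules, tap-aligned step-sorted trial splitting,
response curves (the difference in mean lateral finger velocity between the
two sets as a function of time from the selected step), peak response gains,
and step-sorted tapping-error differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .errors import InvalidSpecError, NoTapError
from .finger import SAMPLE_DT, FingerTrajectory
from .targets import FRAME_DT, TargetTrajectory

#: Savitzky-Golay window (9 samples = 8 ms either side) and polynomial order
SG_WINDOW = 9
SG_ORDER = 2

#: tap-detection thresholds: impact acceleration away from the screen and the
#: maximum finger-screen distance at the tap
TAP_ACCEL_THRESHOLD = 50_000.0  # mm/s^2 (50 m/s^2)
TAP_MAX_HEIGHT = 5.0  # mm

#: exclusion rules: taps after the target disappeared, and gaps in the
#: marker data longer than 20 ms
HIT_WINDOW_S = 0.7
MAX_GAP_S = 0.020


@dataclass(frozen=True)
class SmoothedKinematics:
    """Locally quadratic estimates of lateral position and velocity."""

    position: np.ndarray
    velocity: np.ndarray


def savgol_kinematics(samples: np.ndarray, dt: float = SAMPLE_DT) -> SmoothedKinematics:
    """Second-order Savitzky–Golay estimates over a 9-sample window.

    Exactly reproduces any quadratic input (position and its derivative); the
    edge windows are handled by refitting the edge polynomial.
    """
    x = np.asarray(samples, dtype=float)
    if len(x) < SG_WINDOW:
        raise InvalidSpecError(f"need at least {SG_WINDOW} samples")
    if np.any(~np.isfinite(x)):
        raise InvalidSpecError("missing samples must be interpolated first")
    pos = savgol_filter(x, SG_WINDOW, SG_ORDER, mode="interp")
    vel = savgol_filter(x, SG_WINDOW, SG_ORDER, deriv=1, delta=dt, mode="interp")
    return SmoothedKinematics(pos, vel)


@dataclass(frozen=True)
class TapEvent:
    """Detected tap: time, index, lateral position, and detection mode
    (impact ``acceleration`` or the ``z_minimum`` fallback for gentle taps)."""

    tap_time: float
    tap_index: int
    tap_position: float
    mode: str


def detect_tap(finger: FingerTrajectory) -> TapEvent:
    """First sample at which the three-sample displacement-difference
    acceleration exceeds 50 m/s² away from the screen while the finger is
    below 5 mm and was moving toward the screen; falls back to the minimum
    finger height if the impact was too gentle to cross the threshold."""
    z = np.asarray(finger.z, dtype=float)
    dt = finger.sample_interval
    if np.nanmin(z) >= TAP_MAX_HEIGHT:
        raise NoTapError("finger never came within 5 mm of the screen")
    d = np.diff(z)  # displacement between consecutive samples
    accel = (d[1:] - d[:-1]) / dt**2  # centred on samples 1 .. n-2
    toward = d[:-1] < 0  # moving toward the screen beforehand
    near = z[1:-1] < TAP_MAX_HEIGHT
    hits = np.nonzero((accel > TAP_ACCEL_THRESHOLD) & toward & near)[0]
    if len(hits):
        i = int(hits[0] + 1)
        mode = "acceleration"
    else:
        # gentle tap: minimum height after the reach apex (the finger starts
        # on the screen, so the pre-movement samples must be excluded)
        apex = int(np.nanargmax(z))
        i = apex + int(np.nanargmin(z[apex:]))
        mode = "z_minimum"
    return TapEvent(float(finger.times[i]), i, float(finger.x[i]), mode)


@dataclass
class TrialRecord:
    """One trial: finger samples, the target trajectory, and annotations."""

    trial_id: int
    finger: FingerTrajectory | None
    target: TargetTrajectory
    tap: TapEvent | None = None
    kinematics: SmoothedKinematics | None = None
    meta: dict = field(default_factory=dict)

    @property
    def tap_time(self) -> float:
        if self.tap is not None:
            return self.tap.tap_time
        if self.finger is not None:
            return self.finger.tap_time
        return float(self.meta["tap_time"])

    def target_at_tap(self) -> float:
        """Target position at the tap, linearly interpolated within the frame."""
        return self.target.position_at(self.tap_time)

    def tapping_error(self) -> float:
        """Signed lateral difference between tap and target at the tap."""
        if self.tap is None:
            raise InvalidSpecError("trial has no detected tap")
        return self.tap.tap_position - self.target_at_tap()


def _interpolate_gaps(a: np.ndarray, times: np.ndarray) -> np.ndarray:
    bad = ~np.isfinite(a)
    if not bad.any():
        return a
    out = a.copy()
    out[bad] = np.interp(times[bad], times[~bad], a[~bad])
    return out


def _longest_gap_s(finger: FingerTrajectory) -> float:
    bad = ~(np.isfinite(finger.x) & np.isfinite(finger.y) & np.isfinite(finger.z))
    if not bad.any():
        return 0.0
    # length of the longest run of missing samples
    runs = np.diff(np.nonzero(np.diff(np.concatenate(([0], bad.view(np.int8), [0]))))[0])[::2]
    return float(runs.max() * finger.sample_interval)


def exclude_trials(
    trials: list[TrialRecord],
    hit_window_s: float = HIT_WINDOW_S,
    max_gap_s: float = MAX_GAP_S,
) -> tuple[list[TrialRecord], dict]:
    """Apply the exclusion rules: drop trials tapped after the target
    disappeared and trials with marker gaps longer than 20 ms; shorter gaps
    are linearly interpolated.  Returns the kept trials and a report of
    exclusion counts per rule."""
    kept: list[TrialRecord] = []
    report = {"late_tap": 0, "gap": 0, "no_tap": 0, "kept": 0}
    for tr in trials:
        f = tr.finger
        if f is None:
            kept.append(tr)
            report["kept"] += 1
            continue
        if _longest_gap_s(f) > max_gap_s:
            report["gap"] += 1
            continue
        x = _interpolate_gaps(np.asarray(f.x, float), f.times)
        y = _interpolate_gaps(np.asarray(f.y, float), f.times)
        z = _interpolate_gaps(np.asarray(f.z, float), f.times)
        f = FingerTrajectory(f.times, x, y, z, f.tap_index, f.meta)
        try:
            tap = detect_tap(f)
        except NoTapError:
            report["no_tap"] += 1
            continue
        if tap.tap_time > hit_window_s:
            report["late_tap"] += 1
            continue
        kept.append(TrialRecord(tr.trial_id, f, tr.target, tap, meta=tr.meta))
        report["kept"] += 1
    return kept, report


def _step_at_offset(trial: TrialRecord, step_time_before_tap: float) -> float | None:
    """Size (mm) of the target step at the frame-quantized time before the tap."""
    j = int(round(step_time_before_tap / FRAME_DT))
    tap_frame = int(round(trial.tap_time / FRAME_DT))
    idx = tap_frame - j  # step between frames idx-1 and idx
    steps = trial.target.step_sizes
    if idx < 1 or idx > len(steps):
        return None
    return float(steps[idx - 1])


def split_by_step(
    trials: list[TrialRecord],
    step_time_before_tap: float,
    key: str = "direction",
) -> tuple[list[TrialRecord], list[TrialRecord]]:
    """Sort tap-aligned trials into two sets by the direction (sign) or size
    of the step at one time before the tap.  Returns (rightward-or-large,
    leftward-or-small); trials without a step at that time are dropped."""
    if key not in ("direction", "size"):
        raise InvalidSpecError("key must be 'direction' or 'size'")
    values = [(tr, _step_at_offset(tr, step_time_before_tap)) for tr in trials]
    values = [(tr, v) for tr, v in values if v is not None]
    if key == "direction":
        threshold = 0.0
    else:
        steps = [v for _, v in values]
        threshold = (min(steps) + max(steps)) / 2.0
    high = [tr for tr, v in values if v > threshold]
    low = [tr for tr, v in values if v < threshold]
    return high, low


@dataclass(frozen=True)
class ResponseCurve:
    """Tap-aligned mean differences between the two step-sorted trial sets,
    as functions of time from the selected step."""

    step_time_before_tap: float
    time_from_step: np.ndarray
    dpos: np.ndarray  # mean lateral position difference (mm)
    dvel: np.ndarray  # the "response": mean lateral velocity difference (mm/s)
    n_high: int
    n_low: int


def _ensure_kinematics(tr: TrialRecord) -> SmoothedKinematics:
    if tr.kinematics is None:
        tr.kinematics = savgol_kinematics(tr.finger.x, tr.finger.sample_interval)
    return tr.kinematics


def _mean_aligned(trials, step_time_before_tap, t_rel):
    """Mean smoothed position/velocity over trials at tap-aligned times
    ``tap - step_time + t_rel``; samples outside a trial are ignored."""
    pos_sum = np.zeros_like(t_rel)
    vel_sum = np.zeros_like(t_rel)
    count = np.zeros_like(t_rel)
    for tr in trials:
        kin = _ensure_kinematics(tr)
        times = tr.finger.times
        t_query = tr.tap_time - step_time_before_tap + t_rel
        ok = (t_query >= times[0]) & (t_query <= tr.tap_time)
        pos_sum[ok] += np.interp(t_query[ok], times, kin.position)
        vel_sum[ok] += np.interp(t_query[ok], times, kin.velocity)
        count[ok] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        return pos_sum / count, vel_sum / count, count


def response_curves(
    trials: list[TrialRecord],
    step_times: list[float],
    key: str = "direction",
    t_before: float = 0.1,
) -> list[ResponseCurve]:
    """Response curves for the selected step times: for each, split the
    trials, and take the difference of the tap-aligned mean lateral position
    and velocity between the two sets, from ``t_before`` before the step to
    the step time itself (the tap)."""
    curves = []
    for s in step_times:
        high, low = split_by_step(trials, s, key)
        t_rel = np.arange(-t_before, s + SAMPLE_DT / 2, SAMPLE_DT)
        ph, vh, nh = _mean_aligned(high, s, t_rel)
        pl, vl, nl = _mean_aligned(low, s, t_rel)
        curves.append(
            ResponseCurve(s, t_rel, ph - pl, vh - vl, len(high), len(low))
        )
    return curves


def peak_gain(curve_sets: list[list[ResponseCurve]], step_difference: float) -> dict[float, float]:
    """Peak response gain per step time: the response divided by the step-size
    difference between the two sets, averaged across participant-analogs
    (one curve list per participant) before taking the peak over time."""
    if not curve_sets:
        raise InvalidSpecError("no curves given")
    out: dict[float, float] = {}
    by_time: dict[float, list[ResponseCurve]] = {}
    for curves in curve_sets:
        for c in curves:
            by_time.setdefault(c.step_time_before_tap, []).append(c)
    for s, cs in by_time.items():
        n = min(len(c.dvel) for c in cs)
        stacked = np.vstack([c.dvel[:n] / step_difference for c in cs])
        any_finite = np.isfinite(stacked).any(axis=0)
        mean_gain = np.nanmean(stacked[:, any_finite], axis=0)
        out[s] = float(np.nanmax(mean_gain))
    return out


def estimate_latency(curve: ResponseCurve, fraction: float = 0.25) -> float:
    """Response latency estimated from a response curve: the first time from
    the step at which the velocity difference exceeds ``fraction`` of its
    peak (linearly interpolated between samples).  Only times at or after the
    step are searched, so baseline noise before the step cannot trigger it."""
    after = curve.time_from_step >= 0.0
    t = curve.time_from_step[after]
    v = curve.dvel[after]
    peak = np.nanmax(v)
    if not np.isfinite(peak) or peak <= 0:
        raise InvalidSpecError("response curve has no positive peak")
    threshold = fraction * peak
    above = np.nonzero(v >= threshold)[0]
    if not len(above):
        raise InvalidSpecError("threshold never crossed")
    i = int(above[0])
    if i == 0:
        return float(t[0])
    frac = (threshold - v[i - 1]) / (v[i] - v[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def error_split(
    trials: list[TrialRecord], step_times: list[float], key: str = "direction"
) -> pd.DataFrame:
    """Mean signed tapping-error difference between the step-sorted sets per
    step time (the step-sorted twin of the response curves)."""
    rows = []
    for s in step_times:
        high, low = split_by_step(trials, s, key)
        if not high or not low:
            rows.append(dict(step_time_before_tap_s=s, error_diff_mm=float("nan"),
                             n_high=len(high), n_low=len(low)))
            continue
        eh = np.mean([tr.tapping_error() for tr in high])
        el = np.mean([tr.tapping_error() for tr in low])
        rows.append(dict(step_time_before_tap_s=s, error_diff_mm=float(eh - el),
                         n_high=len(high), n_low=len(low)))
    return pd.DataFrame(rows)


def previous_trial_splits(trials: list[TrialRecord], mean_velocity_ref: float) -> dict[str, float]:
    """Observed-error differences after splitting by previous-trial
    predictors: its mean target velocity (vs the scheme mean, ties dropped),
    its mean velocity over the last 200 ms, and its tapping-error sign.
    Trials must be in session order; the first is skipped."""
    n_last = round(0.2 / FRAME_DT)
    prev_mean, prev_last, prev_err, cur_err = [], [], [], []
    for prev, cur in zip(trials[:-1], trials[1:]):
        shown = prev.target.step_velocities[: int(round(prev.tap_time / FRAME_DT))]
        prev_mean.append(float(shown.mean()))
        prev_last.append(float(shown[-n_last:].mean()))
        prev_err.append(prev.tapping_error())
        cur_err.append(cur.tapping_error())
    cur = np.asarray(cur_err)
    out = {}
    for name, vals, ref, sign in (
        ("mean_velocity", np.asarray(prev_mean), mean_velocity_ref, 1.0),
        ("last200_velocity", np.asarray(prev_last), mean_velocity_ref, 1.0),
        ("error_sign", np.asarray(prev_err), 0.0, -1.0),
    ):
        hi, lo = cur[vals > ref], cur[vals < ref]
        out[name] = sign * (float(hi.mean()) - float(lo.mean())) if len(hi) and len(lo) else float("nan")
    return out
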