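"""Lateral target-motion generators for the five tapping experiments.

Targets are rendered at 120 Hz; between consecutive frames the target makes a
small lateral step.  Depending on the experiment the steps form a symmetric
random walk (jitter about a fixed position), a drifting walk (jitter added to
a constant rightward velocity), or a smooth constant-acceleration trajectory.

Units and conventions
---------------------
Positions are in mm with the screen centre as lateral origin and rightward
positive; times are in seconds.  A step of ``s`` mm per frame corresponds to a
per-frame velocity of ``s * 120`` mm/s (e.g. 5 mm/frame = 600 mm/s = 60 cm/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidSpecError

#: display frame rate (Hz) and frame interval (s)
FRAME_RATE = 120.0
FRAME_DT = 1.0 / FRAME_RATE

#: half-width of the 1.25 m screen (mm)
SCREEN_HALF_WIDTH = 625.0

#: the constant-acceleration trajectories pass 300 mm beyond the screen
#: centre (i.e. 325 mm from the approached edge) 700 ms after appearing
ACCEL_MAGNITUDE = 400.0  # mm/s^2
CONSTRAINT_TIME = 0.7  # s
CONSTRAINT_POSITION = 300.0  # mm past screen centre

#: initial distance from screen centre (mm) by speed class
INITIAL_OFFSET = {"slow": 300.0, "fast": 400.0}

#: random-walk step of the stationary-target experiment: 1/6 of the 10 mm
#: target radius, i.e. a per-frame velocity of 20 cm/s
RANDOM_WALK_STEP = 10.0 / 6.0


@dataclass(frozen=True)
class FrameGrid:
    """Uniform 120 Hz frame grid for one trial."""

    n_frames: int
    frame_interval: float = FRAME_DT

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise InvalidSpecError(f"n_frames must be >= 1, got {self.n_frames}")
        if self.frame_interval <= 0:
            raise InvalidSpecError("frame_interval must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass(frozen=True)
class TargetTrajectory:
    """Per-frame lateral target positions and step velocities for one trial.

    ``positions`` has one entry per frame; ``step_velocities`` has one entry
    per inter-frame step, so ``len(step_velocities) == len(positions) - 1``
    and ``positions[k + 1] - positions[k] == step_velocities[k] * dt``.
    """

    frame_times: np.ndarray
    positions: np.ndarray
    step_velocities: np.ndarray
    truncated: bool = False

    def __post_init__(self) -> None:
        n = len(self.positions)
        if n < 1:
            raise InvalidSpecError("trajectory needs at least one frame")
        if len(self.frame_times) != n or len(self.step_velocities) != n - 1:
            raise InvalidSpecError("inconsistent trajectory array lengths")

    @classmethod
    def from_steps(
        cls, start_position: float, steps_mm: np.ndarray, *, truncated: bool = False
    ) -> "TargetTrajectory":
        """Build a trajectory from its start position and per-frame steps (mm)."""
        steps_mm = np.asarray(steps_mm, dtype=float)
        positions = np.concatenate(([start_position], start_position + np.cumsum(steps_mm)))
        times = np.arange(len(positions)) * FRAME_DT
        return cls(times, positions, steps_mm * FRAME_RATE, truncated=truncated)

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    @property
    def step_sizes(self) -> np.ndarray:
        """Per-frame steps in mm."""
        return self.step_velocities * FRAME_DT

    def position_at(self, t: float) -> float:
        """Target position at an arbitrary time, linearly interpolated within
        the current frame and linearly extrapolated beyond the sampled range
        (the target "would have" continued at its last step velocity)."""
        times = self.frame_times
        if t <= times[0]:
            v = self.step_velocities[0] if len(self.step_velocities) else 0.0
            return float(self.positions[0] + v * (t - times[0]))
        if t >= times[-1]:
            v = self.step_velocities[-1] if len(self.step_velocities) else 0.0
            return float(self.positions[-1] + v * (t - times[-1]))
        return float(np.interp(t, times, self.positions))


@dataclass(frozen=True)
class StepScheme:
    """Distribution of per-frame steps: options (mm), weights, and an optional
    deterministic prefix imposed on the first frames."""

    step_options: tuple[float, ...]
    probabilities: tuple[float, ...] | None = None
    fixed_prefix: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not self.step_options:
            raise InvalidSpecError("step_options must be nonempty")
        p = self._p()
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise InvalidSpecError("probabilities must be nonnegative and sum to 1")
        if len(p) != len(self.step_options):
            raise InvalidSpecError("probabilities must match step_options")

    def _p(self) -> np.ndarray:
        if self.probabilities is None:
            k = len(self.step_options)
            return np.full(k, 1.0 / k)
        return np.asarray(self.probabilities, dtype=float)

    @property
    def mean_step(self) -> float:
        return float(np.dot(self.step_options, self._p()))

    @property
    def mean_velocity(self) -> float:
        """Expected per-frame velocity in mm/s."""
        return self.mean_step * FRAME_RATE

    def draw_steps(self, n_frames: int, rng: np.random.Generator) -> np.ndarray:
        """Draw the n_frames - 1 steps of a trial: the fixed prefix followed by
        i.i.d. draws from the step options."""
        n_steps = n_frames - 1
        if len(self.fixed_prefix) > n_steps:
            raise InvalidSpecError("fixed_prefix longer than the trial")
        prefix = np.asarray(self.fixed_prefix, dtype=float)
        n_random = n_steps - len(prefix)
        random_part = rng.choice(np.asarray(self.step_options), size=n_random, p=self._p())
        return np.concatenate([prefix, random_part])


def make_random_walk(
    n_frames: int,
    step_length: float = RANDOM_WALK_STEP,
    seed: int | np.random.Generator = 0,
    start_position: float = 0.0,
) -> TargetTrajectory:
    """Symmetric random-walk jitter: each frame the target steps ``step_length``
    mm leftward or rightward with probability 1/2 (the stationary-target
    condition; 1.67 mm steps correspond to a per-frame velocity of 20 cm/s)."""
    if n_frames < 1:
        raise InvalidSpecError(f"n_frames must be >= 1, got {n_frames}")
    if step_length <= 0:
        raise InvalidSpecError("step_length must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    steps = rng.choice([-step_length, step_length], size=n_frames - 1)
    return TargetTrajectory.from_steps(start_position, steps)


def make_drifting_walk(
    n_frames: int,
    step_options,
    probabilities=None,
    fixed_prefix=(),
    seed: int | np.random.Generator = 0,
    start_position: float = 0.0,
) -> TargetTrajectory:
    """Drifting walk: per-frame steps drawn i.i.d. from ``step_options`` (after
    an optional deterministic prefix), all sharing the drift sign.  The moving
    target conditions use rightward steps of 3.33 or 6.67 mm (40 or 80 cm/s),
    averaging 60 cm/s."""
    if n_frames < 1:
        raise InvalidSpecError(f"n_frames must be >= 1, got {n_frames}")
    scheme = StepScheme(tuple(step_options), None if probabilities is None else tuple(probabilities), tuple(fixed_prefix))
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return TargetTrajectory.from_steps(start_position, scheme.draw_steps(n_frames, rng))


#: per-frame velocity pairs (cm/s) by jitter-variability level
VARIABILITY_SPEEDS_CM_S = {
    "none": (60.0,),
    "small": (50.0, 70.0),
    "standard": (40.0, 80.0),
    "large": (25.0, 95.0),
}


def variability_scheme(level: str) -> StepScheme:
    """Equiprobable step scheme for a jitter-variability level.

    ``standard`` reproduces the 40/80 cm/s steps (3.33/6.67 mm) of the moving
    target conditions; ``none`` degenerates to a constant 60 cm/s."""
    try:
        speeds = VARIABILITY_SPEEDS_CM_S[level]
    except KeyError:
        raise InvalidSpecError(f"unknown variability level {level!r}") from None
    steps = tuple(v * 10.0 / FRAME_RATE for v in speeds)  # cm/s -> mm per frame
    return StepScheme(steps)


#: start positions for the initial-speed (first 100 ms fast/slow) conditions,
#: chosen so both prefixes end 140 mm left of the screen centre after 12 frames
INITIAL_SPEED_START = {"slow": -180.0, "fast": -220.0}
INITIAL_SPEED_PREFIX = {"slow": (10.0 / 3.0,) * 12, "fast": (20.0 / 3.0,) * 12}


def make_initial_speed_trial(
    initial: str,
    n_frames: int,
    seed: int | np.random.Generator = 0,
    level: str = "standard",
) -> TargetTrajectory:
    """One trial of the initial-speed design: the first 12 steps are all small
    (slow, 40 cm/s, start −180 mm) or all large (fast, 80 cm/s, start −220 mm),
    so that every target is 140 mm left of centre after 100 ms; subsequent
    steps follow the given variability scheme."""
    if initial not in INITIAL_SPEED_START:
        raise InvalidSpecError(f"initial must be 'slow' or 'fast', got {initial!r}")
    scheme = variability_scheme(level)
    return make_drifting_walk(
        n_frames,
        scheme.step_options,
        fixed_prefix=INITIAL_SPEED_PREFIX[initial],
        seed=seed,
        start_position=INITIAL_SPEED_START[initial],
    )


@dataclass(frozen=True)
class AccelTrajectorySpec:
    """One of the eight constant-acceleration trajectory kinds.

    ``direction`` is +1 (rightward) or −1 (leftward); ``acceleration`` is the
    signed rate along the motion direction (+400 mm/s² accelerating, −400
    decelerating); ``speed_class`` selects the 300 mm (slow) or 400 mm (fast)
    initial offset from the screen centre, on the side opposite the motion.
    """

    direction: int
    acceleration: float
    speed_class: str

    def __post_init__(self) -> None:
        if self.direction not in (-1, 1):
            raise InvalidSpecError("direction must be +1 or -1")
        if abs(abs(self.acceleration) - ACCEL_MAGNITUDE) > 1e-9:
            raise InvalidSpecError(f"|acceleration| must be {ACCEL_MAGNITUDE} mm/s^2")
        if self.speed_class not in INITIAL_OFFSET:
            raise InvalidSpecError("speed_class must be 'slow' or 'fast'")

    @property
    def initial_offset(self) -> float:
        return INITIAL_OFFSET[self.speed_class]

    @property
    def initial_position(self) -> float:
        """Lateral start position (opposite side of the motion direction)."""
        return -self.direction * self.initial_offset

    @property
    def accelerating(self) -> bool:
        return self.acceleration > 0

    @property
    def label(self) -> str:
        return (
            ("R" if self.direction > 0 else "L")
            + ("+" if self.accelerating else "-")
            + self.speed_class
        )


def solve_initial_speed(spec: AccelTrajectorySpec) -> float:
    """Initial speed (mm/s, along the motion direction) such that the target is
    300 mm past the screen centre 700 ms after appearing:
    ``d = v0*t + a*t^2/2`` with ``d = initial_offset + 300`` and ``t = 0.7 s``."""
    d = spec.initial_offset + CONSTRAINT_POSITION
    v0 = (d - 0.5 * spec.acceleration * CONSTRAINT_TIME**2) / CONSTRAINT_TIME
    if v0 <= 0:
        raise InvalidSpecError("constraints admit no positive initial speed")
    return v0


def make_accel_trajectory(spec: AccelTrajectorySpec, n_frames: int = 120) -> TargetTrajectory:
    """Constant-acceleration trajectory sampled at 120 Hz.

    Per-frame step velocities are evaluated at frame midpoints so the discrete
    position sequence matches the continuous kinematics exactly.  If the
    trajectory leaves the screen before ``n_frames`` the ``truncated`` flag is
    set (positions are kept, not clipped)."""
    if n_frames < 1:
        raise InvalidSpecError(f"n_frames must be >= 1, got {n_frames}")
    v0 = solve_initial_speed(spec)
    t_mid = (np.arange(n_frames - 1) + 0.5) * FRAME_DT
    step_velocities = spec.direction * (v0 + spec.acceleration * t_mid)
    traj = TargetTrajectory.from_steps(spec.initial_position, step_velocities * FRAME_DT)
    truncated = bool(np.any(np.abs(traj.positions) > SCREEN_HALF_WIDTH))
    if truncated:
        traj = TargetTrajectory(
            traj.frame_times, traj.positions, traj.step_velocities, truncated=True
        )
    return traj


#: the eight trajectory kinds: direction x acceleration sign x speed class
ALL_ACCEL_SPECS = tuple(
    AccelTrajectorySpec(d, sa * ACCEL_MAGNITUDE, sc)
    for d in (1, -1)
    for sa in (1, -1)
    for sc in ("slow", "fast")
)


@dataclass(frozen=True)
class BlockSpec:
    """An ordered list of trajectory kinds forming one block of trials."""

    block_kind: str
    trial_specs: tuple[AccelTrajectorySpec, ...] = field(default_factory=tuple)

    @property
    def n_trials(self) -> int:
        return len(self.trial_specs)


def _specs_where(direction=None, accelerating=None, speed_class=None):
    out = []
    for s in ALL_ACCEL_SPECS:
        if direction is not None and s.direction != direction:
            continue
        if accelerating is not None and s.accelerating != accelerating:
            continue
        if speed_class is not None and s.speed_class != speed_class:
            continue
        out.append(s)
    return out


def _experimental_pairs():
    """The four pairs of grouped blocks (each member: 4 kinds x 3 repeats)."""
    return {
        "acceleration_grouped": (
            _specs_where(accelerating=True),
            _specs_where(accelerating=False),
        ),
        "error_grouped": (
            _specs_where(direction=1, accelerating=False) + _specs_where(direction=-1, accelerating=True),
            _specs_where(direction=1, accelerating=True) + _specs_where(direction=-1, accelerating=False),
        ),
        "speed_grouped": (
            _specs_where(speed_class="slow"),
            _specs_where(speed_class="fast"),
        ),
        "direction_grouped": (
            _specs_where(direction=1),
            _specs_where(direction=-1),
        ),
    }


def make_session_blocks(session_seed: int | np.random.Generator) -> list[BlockSpec]:
    """One 168-trial session: 9 reference blocks (each of the 8 trajectory
    kinds once, shuffled) alternating with the 8 grouped blocks (4 kinds x 3
    repeats, shuffled) in random order."""
    rng = (
        session_seed
        if isinstance(session_seed, np.random.Generator)
        else np.random.default_rng(session_seed)
    )
    experimental = []
    for kind, (a, b) in _experimental_pairs().items():
        for member in (a, b):
            specs = [s for s in member for _ in range(3)]
            order = rng.permutation(len(specs))
            experimental.append(BlockSpec(kind, tuple(specs[i] for i in order)))
    exp_order = rng.permutation(len(experimental))

    blocks: list[BlockSpec] = []
    for i in range(9):
        order = rng.permutation(len(ALL_ACCEL_SPECS))
        blocks.append(BlockSpec("reference", tuple(ALL_ACCEL_SPECS[j] for j in order)))
        if i < 8:
            blocks.append(experimental[exp_order[i]])
    return blocks


def make_alternating_2012_blocks(
    n_blocks: int, session_seed: int | np.random.Generator
) -> list[BlockSpec]:
    """Replication scenario: rightward-moving targets only, in alternating
    12-trial blocks of all-accelerating and all-decelerating trajectories
    (slow and fast kinds, 6 repeats each, shuffled within the block)."""
    rng = (
        session_seed
        if isinstance(session_seed, np.random.Generator)
        else np.random.default_rng(session_seed)
    )
    blocks = []
    for i in range(n_blocks):
        kinds = _specs_where(direction=1, accelerating=(i % 2 == 0))
        specs = [s for s in kinds for _ in range(6)]
        order = rng.permutation(len(specs))
        blocks.append(BlockSpec("alternating_2012", tuple(specs[i] for i in order)))
    return blocks
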