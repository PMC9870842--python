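import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import interceptsim as isim
from interceptsim.errors import InvalidSpecError
from interceptsim.targets import FRAME_DT, INITIAL_SPEED_PREFIX


class TestRandomWalk:
    def test_step_velocity_magnitude_is_20_cm_s(self):
        traj = isim.make_random_walk(61, step_length=1.667, seed=0)
        assert np.allclose(np.abs(traj.step_velocities), 1.667 * 120.0)

    def test_degenerate_single_frame(self):
        traj = isim.make_random_walk(1, seed=0)
        assert traj.n_frames == 1 and len(traj.step_velocities) == 0

    def test_invalid_length_rejected(self):
        with pytest.raises(InvalidSpecError):
            isim.make_random_walk(0, seed=0)

    def test_final_position_moments_match_closed_form(self):
        """Mean 0 and variance n*step^2 of the unbiased random walk."""
        rng = np.random.default_rng(1)
        step = 5.0 / 3.0
        finals = np.array(
            [isim.make_random_walk(61, step_length=step, seed=rng).positions[-1]
             for _ in range(10_000)]
        )
        expected_var = 60 * step**2
        assert abs(finals.mean()) < 3 * np.sqrt(expected_var / len(finals))
        assert abs(finals.var() / expected_var - 1.0) < 0.05

    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(2, 120))
    @settings(max_examples=25, deadline=None)
    def test_positions_integrate_steps_exactly(self, seed, n):
        traj = isim.make_random_walk(n, seed=seed)
        rebuilt = traj.positions[0] + np.cumsum(traj.step_velocities * FRAME_DT)
        assert np.allclose(rebuilt, traj.positions[1:], rtol=0, atol=1e-12)


class TestDriftingWalk:
    def test_standard_scheme_velocities_average_60_cm_s(self):
        scheme = isim.variability_scheme("standard")
        traj = isim.make_drifting_walk(1001, scheme.step_options, seed=0)
        assert set(np.round(traj.step_velocities, 6)) <= {400.0, 800.0}
        assert scheme.mean_velocity == pytest.approx(600.0)

    def test_degenerate_no_variability(self):
        scheme = isim.variability_scheme("none")
        traj = isim.make_drifting_walk(61, scheme.step_options, seed=0)
        assert np.allclose(traj.step_velocities, 600.0)

    def test_bad_probabilities_rejected(self):
        with pytest.raises(InvalidSpecError):
            isim.make_drifting_walk(10, (3.33, 6.67), probabilities=(0.6, 0.6), seed=0)

    def test_initial_speed_prefixes_meet_at_frame_12(self):
        """Slow (from -180 mm) and fast (from -220 mm) prefixes both end
        140 mm left of the screen centre after 100 ms."""
        slow = isim.make_initial_speed_trial("slow", 61, seed=0)
        fast = isim.make_initial_speed_trial("fast", 61, seed=0)
        assert slow.positions[12] == pytest.approx(-140.0)
        assert fast.positions[12] == pytest.approx(-140.0)


class TestVariabilityScheme:
    @pytest.mark.parametrize(
        "level,expected_cm_s",
        [("none", (60,)), ("small", (50, 70)), ("standard", (40, 80)), ("large", (25, 95))],
    )
    def test_levels_map_to_velocities(self, level, expected_cm_s):
        scheme = isim.variability_scheme(level)
        velocities = sorted(s * 120.0 / 10.0 for s in scheme.step_options)
        assert velocities == pytest.approx(sorted(expected_cm_s))

    def test_large_level_velocity_sd(self):
        scheme = isim.variability_scheme("large")
        v_cm = np.array(scheme.step_options) * 120.0 / 10.0
        assert np.std(v_cm) == pytest.approx(35.0)

    def test_unknown_level_rejected(self):
        with pytest.raises(InvalidSpecError):
            isim.variability_scheme("huge")


class TestAccelTrajectories:
    def test_initial_speed_solves_kinematic_constraint(self):
        spec = isim.AccelTrajectorySpec(1, 400.0, "slow")
        v0 = isim.solve_initial_speed(spec)
        assert v0 == pytest.approx((600.0 - 98.0) / 0.7)
        # oracle: forward-integrate and check the 700 ms position
        d = v0 * 0.7 + 0.5 * 400.0 * 0.7**2
        assert d == pytest.approx(600.0)

    def test_fast_minus_slow_speed_is_about_14_cm_s(self):
        for accel in (400.0, -400.0):
            fast = isim.solve_initial_speed(isim.AccelTrajectorySpec(1, accel, "fast"))
            slow = isim.solve_initial_speed(isim.AccelTrajectorySpec(1, accel, "slow"))
            assert fast - slow == pytest.approx(100.0 / 0.7)

    def test_position_at_700_ms_is_300_mm_past_centre(self):
        for spec in isim.ALL_ACCEL_SPECS:
            traj = isim.make_accel_trajectory(spec, n_frames=120)
            frame_700 = round(0.7 / FRAME_DT)
            assert traj.positions[frame_700] == pytest.approx(spec.direction * 300.0, abs=1e-9)

    def test_deceleration_shrinks_speed_per_frame(self):
        spec = isim.AccelTrajectorySpec(1, -400.0, "slow")
        traj = isim.make_accel_trajectory(spec, n_frames=60)
        dv = np.diff(traj.step_velocities)
        assert np.allclose(dv, -400.0 * FRAME_DT)

    def test_leftward_mirrors_rightward(self):
        right = isim.make_accel_trajectory(isim.AccelTrajectorySpec(1, 400.0, "fast"), 100)
        left = isim.make_accel_trajectory(isim.AccelTrajectorySpec(-1, 400.0, "fast"), 100)
        assert np.allclose(left.positions, -right.positions)

    def test_screen_exit_is_flagged(self):
        spec = isim.AccelTrajectorySpec(1, 400.0, "fast")
        assert make_truncated(spec).truncated
        assert not isim.make_accel_trajectory(spec, n_frames=60).truncated


def make_truncated(spec):
    return isim.make_accel_trajectory(spec, n_frames=120)


class TestSessionBlocks:
    def test_session_counts(self):
        blocks = isim.make_session_blocks(0)
        assert len(blocks) == 17
        assert sum(b.n_trials for b in blocks) == 168
        kinds = [b.block_kind for b in blocks]
        assert kinds[::2] == ["reference"] * 9

    def test_reference_blocks_contain_each_kind_once(self):
        for block in isim.make_session_blocks(1):
            if block.block_kind == "reference":
                assert sorted(s.label for s in block.trial_specs) == sorted(
                    s.label for s in isim.ALL_ACCEL_SPECS
                )

    def test_grouped_blocks_are_4_kinds_times_3(self):
        for block in isim.make_session_blocks(2):
            if block.block_kind != "reference":
                labels = [s.label for s in block.trial_specs]
                assert len(labels) == 12
                assert all(labels.count(x) == 3 for x in set(labels))

    def test_error_grouped_blocks_push_errors_to_one_side(self):
        """Within an error-grouped block, ignoring the acceleration always
        biases the tap toward the same side: direction x acceleration sign is
        constant across the block."""
        for block in isim.make_session_blocks(3):
            if block.block_kind == "error_grouped":
                signs = {s.direction * (1 if s.accelerating else -1) for s in block.trial_specs}
                assert len(signs) == 1

    def test_alternating_2012_blocks(self):
        blocks = isim.make_alternating_2012_blocks(4, 0)
        for i, b in enumerate(blocks):
            assert all(s.direction == 1 for s in b.trial_specs)
            accels = {s.accelerating for s in b.trial_specs}
            assert accels == {i % 2 == 0}
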