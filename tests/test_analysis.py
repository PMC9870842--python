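import numpy as np
import pytest

import interceptsim as isim
from interceptsim.analysis import _step_at_offset
from interceptsim.errors import InvalidSpecError, NoTapError
from interceptsim.finger import SAMPLE_DT, FingerTrajectory
from interceptsim.targets import FRAME_DT


class TestSavgolKinematics:
    def test_constant_input_recovered_exactly(self):
        kin = isim.savgol_kinematics(np.full(50, 7.5))
        assert np.allclose(kin.position, 7.5)
        assert np.allclose(kin.velocity, 0.0)

    def test_quadratic_input_and_derivative_exact(self):
        t = np.arange(60) * SAMPLE_DT
        a, b, c = 4000.0, -300.0, 12.0
        kin = isim.savgol_kinematics(a * t**2 + b * t + c)
        assert np.allclose(kin.position, a * t**2 + b * t + c, atol=1e-8)
        assert np.allclose(kin.velocity, 2 * a * t + b, atol=1e-6)

    def test_smoothing_reduces_velocity_noise(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.0, 0.5, 400)
        kin = isim.savgol_kinematics(x)
        raw_velocity = np.diff(x) / SAMPLE_DT
        assert kin.velocity.var() < raw_velocity.var()

    def test_too_short_input_rejected(self):
        with pytest.raises(InvalidSpecError):
            isim.savgol_kinematics(np.zeros(5))


class TestDetectTap:
    @staticmethod
    def synth(gentle=False):
        traj = isim.make_random_walk(61, seed=2)
        return isim.synthesize_trial(
            traj, 60, mean_step=0.0, noise_sd=0.0, seed=0, gentle_landing=gentle
        )

    def test_impact_sample_detected(self):
        f = self.synth()
        tap = isim.detect_tap(f)
        assert tap.mode == "acceleration"
        assert abs(tap.tap_index - f.tap_index) <= 1

    def test_gentle_landing_falls_back_to_height_minimum(self):
        f = self.synth(gentle=True)
        tap = isim.detect_tap(f)
        assert tap.mode == "z_minimum"
        assert abs(tap.tap_time - f.tap_time) < 0.01

    def test_finger_far_from_screen_raises(self):
        f = self.synth()
        lifted = FingerTrajectory(f.times, f.x, f.y, f.z + 20.0, f.tap_index)
        with pytest.raises(NoTapError):
            isim.detect_tap(lifted)


class TestExcludeTrials:
    @staticmethod
    def trial_with_gap(trial_id, gap_samples):
        traj = isim.make_random_walk(61, seed=trial_id)
        f = isim.synthesize_trial(traj, 60, mean_step=0.0, noise_sd=0.0, seed=trial_id)
        x = f.x.copy()
        if gap_samples:
            x[100 : 100 + gap_samples] = np.nan
        f = FingerTrajectory(f.times, x, f.y, f.z, f.tap_index)
        return isim.TrialRecord(trial_id, f, traj)

    def test_planted_violations_are_counted(self):
        trials = (
            [self.trial_with_gap(i, 0) for i in range(4)]
            + [self.trial_with_gap(10 + i, 15) for i in range(3)]  # 30 ms gaps
            + [self.trial_with_gap(20 + i, 5) for i in range(2)]  # 10 ms gaps
        )
        kept, report = isim.exclude_trials(trials)
        assert report["gap"] == 3
        assert report["kept"] == 6
        assert len(kept) == 6

    def test_short_gaps_are_interpolated(self):
        kept, _ = isim.exclude_trials([self.trial_with_gap(1, 5)])
        assert np.all(np.isfinite(kept[0].finger.x))

    def test_late_taps_are_excluded(self):
        traj = isim.make_random_walk(121, seed=3)
        f = isim.synthesize_trial(traj, 96, mean_step=0.0, noise_sd=0.0, seed=3)
        _, report = isim.exclude_trials([isim.TrialRecord(0, f, traj)])
        assert report["late_tap"] == 1


class TestSplitByStep:
    @staticmethod
    def target_only_trials(n, rng):
        trials = []
        for i in range(n):
            traj = isim.make_random_walk(61, seed=rng)
            trials.append(
                isim.TrialRecord(i, None, traj, meta={"tap_time": 60 * FRAME_DT})
            )
        return trials

    def test_position_difference_is_twice_step_after_split(self):
        """Splitting by one step's direction leaves a 3.33 mm expected
        target-position difference from that step onward and none before."""
        rng = np.random.default_rng(8)
        trials = self.target_only_trials(10_000, rng)
        s = 0.2  # step 24 frames before the 60-frame tap
        high, low = isim.split_by_step(trials, s)
        split_frame = 60 - 24
        diff = np.mean([t.target.positions for t in high], axis=0) - np.mean(
            [t.target.positions for t in low], axis=0
        )
        step = 5.0 / 3.0
        n = min(len(high), len(low))
        se_per_frame = step * np.sqrt(2.0 / n)
        # before: grows like a random walk bridge; compare at a few frames
        assert abs(diff[split_frame - 1]) < 3 * se_per_frame * np.sqrt(split_frame)
        after = diff[split_frame:] - 2 * step
        assert np.all(np.abs(after) < 4 * se_per_frame * np.sqrt(60))

    def test_split_on_deterministic_prefix_partitions_by_condition(self):
        rng = np.random.default_rng(9)
        trials = []
        for i in range(40):
            cond = "fast" if i % 2 else "slow"
            traj = isim.make_initial_speed_trial(cond, 61, seed=rng)
            trials.append(isim.TrialRecord(i, None, traj, meta={"tap_time": 0.5}))
        high, low = isim.split_by_step(trials, 0.45, key="size")  # frame 6: prefix
        assert all(t.target.step_sizes[0] > 5.0 for t in high)
        assert all(t.target.step_sizes[0] < 5.0 for t in low)
        assert len(high) == len(low) == 20

    def test_step_lookup_respects_frame_quantization(self):
        traj = isim.make_random_walk(61, seed=1)
        tr = isim.TrialRecord(0, None, traj, meta={"tap_time": 60 * FRAME_DT})
        got = _step_at_offset(tr, 10 * FRAME_DT)
        assert got == pytest.approx(traj.step_sizes[49])


class TestPipelineEndToEnd:
    def test_latency_recovered_within_one_frame(self, msd_trial_batch):
        """The analysis recovers the generative 100 ms response latency."""
        curves = isim.response_curves(msd_trial_batch, [0.2, 0.25])
        for c in curves:
            assert isim.estimate_latency(c) == pytest.approx(0.1, abs=FRAME_DT)

    def test_vigour_increases_for_later_steps(self, msd_trial_batch):
        c_late, c_early = isim.response_curves(msd_trial_batch, [0.15, 0.25])
        assert np.nanmax(c_late.dvel) > np.nanmax(c_early.dvel)

    def test_error_pattern_matches_response_model(self, msd_trial_batch):
        """Errors mirror the response dynamics: steps within the latency are
        uncorrected (difference -2x step), early steps are fully corrected,
        and intermediate steps overshoot slightly (non-negative difference)."""
        es = isim.error_split(msd_trial_batch, [0.05, 0.17, 0.35]).set_index(
            "step_time_before_tap_s"
        )
        step = 5.0 / 3.0
        se = np.sqrt(12) * step * np.sqrt(2.0 / 250)
        assert es.loc[0.05, "error_diff_mm"] == pytest.approx(-2 * step, abs=3.5 * se)
        assert es.loc[0.35, "error_diff_mm"] == pytest.approx(0.0, abs=3.5 * se)
        assert es.loc[0.17, "error_diff_mm"] > -3.5 * se

    def test_no_jitter_trials_give_flat_curves(self):
        rng = np.random.default_rng(5)
        trials = []
        for i in range(40):
            traj = isim.make_drifting_walk(61, (5.0,), seed=rng, start_position=-200.0)
            f = isim.synthesize_trial(traj, 60, noise_sd=0.0, seed=rng)
            trials.append(isim.TrialRecord(i, f, traj, tap=isim.detect_tap(f)))
        curves = isim.response_curves(trials, [0.2], key="size")
        assert curves[0].n_high == 0 or curves[0].n_low == 0

    def test_pipeline_is_deterministic(self, msd_trial_batch):
        a = isim.error_split(msd_trial_batch, [0.2])
        b = isim.error_split(msd_trial_batch, [0.2])
        assert a.equals(b)


class TestPeakGain:
    def test_gain_is_scale_invariant(self):
        """Scaling the jitter scales the response; the gain is unchanged."""
        rng = np.random.default_rng(11)

        def batch(step, n=300):
            trials = []
            for i in range(n):
                traj = isim.make_random_walk(61, step_length=step, seed=rng)
                f = isim.synthesize_trial(traj, 60, mean_step=0.0, noise_sd=0.0, seed=rng)
                trials.append(isim.TrialRecord(i, f, traj, tap=isim.detect_tap(f)))
            return trials

        small = isim.response_curves(batch(5.0 / 6.0), [0.2])
        large = isim.response_curves(batch(10.0 / 3.0), [0.2])
        g_small = isim.peak_gain([small], step_difference=2 * 5.0 / 6.0)
        g_large = isim.peak_gain([large], step_difference=2 * 10.0 / 3.0)
        assert g_small[0.2] == pytest.approx(g_large[0.2], rel=0.15)

    def test_truncated_response_peak_is_lower_than_closed_form(self, msd_trial_batch):
        """A step 120 ms before the tap leaves only ~20 ms of response, so the
        measured peak stays below the untruncated closed-form peak."""
        from interceptsim.finger import MSDSpec

        (curve,) = isim.response_curves(msd_trial_batch, [0.12])
        step = 5.0 / 3.0
        spec = MSDSpec(2 * step, 20.0)
        closed_peak = isim.msd_velocity(spec, np.linspace(0, 0.3, 600)).max()
        assert np.nanmax(curve.dvel) < closed_peak
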