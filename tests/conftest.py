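import numpy as np
import pytest

import interceptsim as isim


@pytest.fixture(scope="session")
def msd_trial_batch():
    """Shared batch of synthesized random-walk trials (mass-spring-damper
    responses, fixed 500 ms taps, low noise) for the analysis pipeline tests."""
    rng = np.random.default_rng(42)
    trials = []
    for i in range(500):
        traj = isim.make_random_walk(61, seed=rng)
        finger = isim.synthesize_trial(
            traj, 60, model="msd", mean_step=0.0, seed=rng, noise_sd=0.2
        )
        trials.append(isim.TrialRecord(i, finger, traj, tap=isim.detect_tap(finger)))
    return trials
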