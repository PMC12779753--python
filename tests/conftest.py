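import numpy as np
import pytest

from graspkin import synth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_spec():
    """One participant, one run of 3 balanced blocks."""
    return synth.SessionSpec(
        participants=1, runs_per_participant=1, blocks_per_run=3, trials_per_block=3
    )


def make_trial(noise_sd_mm=0.0, seed=0, grip_type="power", **kwargs):
    """One simulated trial with its (exact) ground truth attached."""
    gt = synth.sample_ground_truth(np.random.default_rng(seed), grip_type)
    trial = synth.simulate_trial(
        gt, noise_sd_mm=noise_sd_mm, seed=seed, **kwargs
    )
    return trial, gt


@pytest.fixture
def noiseless_trial():
    return make_trial(noise_sd_mm=0.0, seed=7)
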