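import numpy as np
import pytest

from thermaffect import SynthConfig, generate_cohort, generate_session


@pytest.fixture(scope="session")
def small_config():
    """A compact but fully realistic study configuration."""
    return SynthConfig(n_participants=3, baseline_frames=4, task_frames=6, seed=11)


@pytest.fixture(scope="session")
def baseline_session(small_config):
    """One baseline session (frames + ground truth) of participant S1."""
    frames, truth = generate_session(small_config, "S1", "baseline", seed=101)
    return frames, truth


@pytest.fixture(scope="session")
def tiny_cohort(small_config):
    """Full 3-participant cohort: 15 sessions with ground truth."""
    return generate_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
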