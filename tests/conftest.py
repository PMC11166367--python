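import numpy as np
import pytest

import fatigability as fg


@pytest.fixture(scope="session")
def default_walk():
    """One simulated walk under the default profile, with ground truth."""
    return fg.simulate_walk(fg.WalkProfile(seed=3))


@pytest.fixture(scope="session")
def decline_walk():
    """Walk with a linear cadence decline 110 -> 90 steps/min."""
    profile = fg.WalkProfile(
        cadence_fn=fg.linear_decline(110.0, 90.0, 300.0), seed=7
    )
    return fg.simulate_walk(profile), profile


@pytest.fixture(scope="session")
def default_cohort():
    """One default (calibrated) cohort of n = 795."""
    return fg.simulate_cohort(fg.default_params(n=795, seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
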