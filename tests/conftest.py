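import numpy as np
import pytest
from hypothesis import settings

import rlelicit as rl

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def space():
    return rl.default_space()


@pytest.fixture
def study_visits():
    return rl.load_study_counts()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def planted_cohort_logs(space):
    """20 deterministic participants sharing the single-peak preference
    teleportation/body/feedback/realistic (utility argmax = code 6)."""
    profiles = [
        rl.PreferenceProfile(np.array([-1.0, 1.0, 1.0, -1.0]))
        for _ in range(20)
    ]
    return rl.run_cohort(space, profiles, n_proposals=24, seed=42)
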