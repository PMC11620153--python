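import numpy as np
import pytest

from emgtap.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny but complete cohort: 2 PD + 2 healthy, one task, one channel."""
    cfg = SimConfig(
        n_pd=2,
        n_healthy=2,
        tasks=("finger_tapping",),
        channels=(("flexors", "left"),),
        seed=7,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort at the generator defaults (6 PD + 7 healthy,
    both tasks, four channels)."""
    return simulate_cohort(SimConfig(seed=5))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
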