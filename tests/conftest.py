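import numpy as np
import pytest

import wakeprob as wp


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_dataset():
    """A small sigmoid-descent night shared by the slower integration tests."""
    return wp.simulate_dataset(
        wp.SimulationScenario(duration=180.0, seed=7, transition_time=90.0,
                              transition_duration=60.0)
    )


@pytest.fixture(scope="session")
def short_fit(short_dataset):
    return wp.run_filter(
        short_dataset.grid, wp.ModelConfig(),
        wp.FilterConfig(n_particles=800), seed=11,
    )
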