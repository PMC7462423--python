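import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_recording(rng):
    """A 5-neuron Poisson recording, 30 s."""
    from spikepid import Recording

    spikes = {
        nid: np.sort(rng.uniform(0, 30.0, size=rng.poisson(3.0 * 30)))
        for nid in range(1, 6)
    }
    return Recording(spikes, duration=30.0, label="fixture")
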