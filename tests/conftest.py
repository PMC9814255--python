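import numpy as np
import pytest

from bpopen import BreathingConfig, EventConfig, gen_event_series


@pytest.fixture(scope="session")
def noiseless_event_series():
    """One breathing-free series with a single 1.2 A/ps ramp event."""
    return gen_event_series(
        BreathingConfig(ou_sigma=0.0, seed=0), EventConfig(speed=1.2, start=14.0)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
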