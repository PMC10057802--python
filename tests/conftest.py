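import numpy as np
import pytest

from eeganomaly import SynthConfig, generate


@pytest.fixture(scope="session")
def small_fixture():
    """A quick 4-channel, 2-minute recording with 2 planted discharges."""
    cfg = SynthConfig(
        n_channels=4,
        duration_s=120,
        n_events=2,
        event_duration_range=(10.0, 12.0),
        seed=7,
    )
    rec, ann = generate(cfg)
    return cfg, rec, ann


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
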