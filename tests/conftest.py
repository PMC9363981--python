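import numpy as np
import pytest

from misinoc import ScenarioConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A fast scenario for engine-level tests."""
    return ScenarioConfig(
        n_citizens=60,
        rounds=6,
        training_regime="upfront",
        broadcaster_condition="biased",
        base_mcs_level="medium",
        seed=42,
    )
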