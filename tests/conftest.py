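import numpy as np
import pytest
from hypothesis import settings

from eegvote.recording import ALPHA, BandDefinition
from eegvote.synthetic import SyntheticSpec, generate_dataset

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_effect_dataset():
    """Compact labeled dataset with a strong alpha effect on two channels."""
    spec = SyntheticSpec(
        n_trials=30, n_channels=6, n_samples=2048,
        effect_channels=(1, 4), effect_band=ALPHA, effect_gain=4.0, seed=11,
    )
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def small_null_dataset():
    spec = SyntheticSpec(
        n_trials=30, n_channels=6, n_samples=2048,
        effect_channels=(1, 4), effect_gain=1.0, seed=13,
    )
    return generate_dataset(spec)


@pytest.fixture
def theta_band():
    return BandDefinition("theta", 4.0, 8.0)
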