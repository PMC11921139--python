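import numpy as np
import pytest

from oxispec.simulate import GeneratorConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_dataset():
    """One full two-group storage study at generator defaults (seed 0)."""
    return generate_dataset(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced study (3 days x 8 samples/group) for fast model tests."""
    return generate_dataset(GeneratorConfig(n_days=3, samples_per_day_per_group=8,
                                            seed=7))
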