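import numpy as np
import pytest

from resight import ModelConfig, datasets


@pytest.fixture()
def fast_config():
    """Reduced sampler settings for unit tests (exactness not required)."""
    return ModelConfig(iterations=3000, burn_in=800)


@pytest.fixture(scope="session")
def grebe():
    return datasets.load_bird("alaotra_grebe")


@pytest.fixture(scope="session")
def petrel():
    return datasets.load_bird("jamaican_petrel")


@pytest.fixture(scope="session")
def starling():
    return datasets.load_bird("pohnpei_starling")


@pytest.fixture()
def rng():
    return np.random.default_rng(20160101)
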