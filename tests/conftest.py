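import numpy as np
import pytest

from scos.model import BackboneConfig
from scos.phantom import PhantomConfig, generate_dataset, generate_slice


@pytest.fixture(scope="session")
def phantom_config():
    return PhantomConfig()


@pytest.fixture(scope="session")
def unrotated_slice(phantom_config):
    return generate_slice(phantom_config, np.random.default_rng(7), angle_deg=0.0)


@pytest.fixture(scope="session")
def rotated_slices(phantom_config):
    return generate_dataset(phantom_config, 12, rotated=True, seed=21)


@pytest.fixture(scope="session")
def small_backbone():
    return BackboneConfig(depth=2, base_filters=3)
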