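import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from gridcolumn import (
    GridModuleParams,
    Network,
    NetworkConfig,
    generate_objects,
    make_feature_encoding,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def baseline_params():
    """The w=6 entorhinal-sparsity baseline module."""
    return GridModuleParams.baseline()


@pytest.fixture
def small_world(rng):
    """A small trained network: 8 objects, pool of 40 features."""
    objects = generate_objects(8, rng=rng)
    encoding = make_feature_encoding(40, rng=rng)
    net = Network(NetworkConfig.default(), encoding)
    net.train(objects, rng)
    return net, objects
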