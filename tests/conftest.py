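import numpy as np
import pytest

from vesselseg import ModelConfig, build_model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cfg():
    """Smallest config exercising all three stages: 64px input, window 2."""
    return ModelConfig(img_size=64, embed_dim=12, depths=(1, 1, 1), heads=(2, 2, 2), window=2)


@pytest.fixture(scope="session")
def tiny_model(tiny_cfg):
    return build_model(tiny_cfg, seed=7)


@pytest.fixture(scope="session")
def tiny_batch():
    g = np.random.default_rng(3)
    return g.uniform(-1.0, 1.0, (2, 64, 64, 3)).astype(np.float32)
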