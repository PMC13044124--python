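import numpy as np
import pytest

from lightsr import LightRepViTSR, ModelConfig, PhantomConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_config():
    """Small x2 single-channel architecture for fast structural tests."""
    return ModelConfig(scale=2, in_channels=1, stem_channels=4, n_blocks=2)


@pytest.fixture(scope="session")
def tiny_model(tiny_config):
    return LightRepViTSR(tiny_config, init_seed=0)


@pytest.fixture(scope="session")
def small_phantoms():
    """Twelve 32x32 phantoms for pipeline-level tests."""
    cfg = PhantomConfig(height=32, width=32, n_seeds=2, branch_depth=2)
    return generate_dataset(12, cfg, base_seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
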