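import numpy as np
import pytest

from graphmil import ModelConfig, SyntheticConfig, generate_bags


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """30 well-separated bags, enough to exercise splits and training."""
    return generate_bags(SyntheticConfig(n_bags=30, seed=11))


@pytest.fixture
def tiny_model_config():
    """Small widths so unit tests stay fast; architecture unchanged."""
    return ModelConfig(feature_dim=16, mlp_hidden=16, aug_dim=16,
                       enc_hidden=8, latent_dim=6, attention_hidden=8,
                       n_kernels=3)
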