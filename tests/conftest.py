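import numpy as np
import pytest

from grrdb.gnet import ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_cfg():
    """4-channel config for loop-oracle comparisons on 8x8 inputs."""
    return ModelConfig(base_channels=4, n_ghost_lka=1, n_rrdb=1,
                       n_dense_per_rrdb=2, n_conv_per_dense=3,
                       ca_reduction=2, n_dab=1)


def zero_all(model):
    """Zero every learnable parameter (weights and biases)."""
    for p in model.parameters():
        p.data = np.zeros_like(p.data)
    return model
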