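import numpy as np
import pytest
from hypothesis import settings

from salicaps.network import LaneConfig, NetworkConfig

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_net():
    """A two-lane network small enough for brute-force oracles."""
    return NetworkConfig(
        lanes=(
            LaneConfig(
                kernel_size=3, n_conv_filters=4, primary_channels=2,
                capsule_dim=3, hidden_capsules=2, routing_iterations=3,
                dropout_rate=0.0,
            ),
            LaneConfig(
                kernel_size=1, n_conv_filters=3, primary_channels=2,
                capsule_dim=2, primary_stride=2, hidden_capsules=3,
                routing_iterations=4, dropout_rate=0.0,
            ),
        ),
        input_len=5,
        input_channels=4,
        dense_units=6,
        l2_coefficient=0.0,
    )
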