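import numpy as np
import pytest

from embodied_gh import (
    Arena,
    ModelConfig,
    default_roles,
    generate_synthetic_connectome,
)


@pytest.fixture(scope="session")
def connectome66():
    return generate_synthetic_connectome(n_nodes=66, seed=1)


@pytest.fixture(scope="session")
def roles66():
    return default_roles(66)


@pytest.fixture
def arena():
    return Arena(width=20.0, height=20.0)


@pytest.fixture
def base_config():
    return ModelConfig(
        coupling=1.0,
        initial_threshold=0.2,
        alpha=0.1,
        rho=0.1,
        epochs=200,
        seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
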