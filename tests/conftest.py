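import numpy as np
import pytest

from dpddi import (
    BENCHMARK_SBM,
    SMALL_SBM,
    DDINetwork,
    EncoderConfig,
    PredictorConfig,
    generate_sbm_network,
)

# tiny configurations for fast structural tests; the benchmark-scale
# configurations live in dpddi.benchmarks
SMOKE_ENCODER = EncoderConfig(hidden_dim=16, embedding_dim=8,
                              learning_rate=0.01, epochs=60, dropout=0.0)
SMOKE_PREDICTOR = PredictorConfig(layer_sizes=(16, 16, 8, 2), epochs=20,
                                  batch_size=20, learning_rate=0.01, dropout=0.0)


@pytest.fixture(scope="session")
def k3():
    return DDINetwork.from_edges(("a", "b", "c"), [(0, 1), (1, 2), (0, 2)])


@pytest.fixture(scope="session")
def two_node():
    return DDINetwork.from_edges(("a", "b"), [(0, 1)])


@pytest.fixture(scope="session")
def sbm30():
    return generate_sbm_network(SMALL_SBM)


@pytest.fixture(scope="session")
def sbm200():
    return generate_sbm_network(BENCHMARK_SBM)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
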