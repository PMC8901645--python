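import numpy as np
import pytest

from claimpt.data_model import build_vocabulary
from claimpt.synthetic_claims import SimulationConfig, simulate_population


@pytest.fixture(scope="session")
def small_bundle():
    """A small simulated corpus shared by unit tests (300 patients)."""
    return simulate_population(SimulationConfig(n_patients=300, seed=42))


@pytest.fixture(scope="session")
def small_vocab(small_bundle):
    return build_vocabulary(small_bundle.records, min_count=1)


@pytest.fixture(scope="session")
def tiny_bundle():
    """A very small corpus with a reduced code space (fast model tests)."""
    config = SimulationConfig(
        n_patients=60,
        n_codes={"DIAG": 40, "PROC": 20, "DRUG": 10},
        n_categories={"DIAG": 4, "PROC": 2, "DRUG": 2},
        seed=7,
    )
    return simulate_population(config)


@pytest.fixture(scope="session")
def tiny_vocab(tiny_bundle):
    return build_vocabulary(tiny_bundle.records, min_count=1)


@pytest.fixture(scope="session")
def tiny_model(tiny_bundle, tiny_vocab):
    from claimpt.encoder import EncoderConfig, ModelParameters, bind_vocab

    params = ModelParameters.init(
        tiny_vocab.total_size,
        tiny_bundle.grouper.total_categories,
        EncoderConfig(d=32, n_heads=4, ffn_dim=32),
        seed=1,
    )
    return bind_vocab(params, tiny_vocab)


def numerical_gradient(f, arr, eps=1e-6):
    """Central-difference gradient of scalar f() with respect to arr."""
    g = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = arr[i]
        arr[i] = old + eps
        fp = f()
        arr[i] = old - eps
        fm = f()
        arr[i] = old
        g[i] = (fp - fm) / (2 * eps)
    return g
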