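import numpy as np
import pytest

from popcode import MaxEntModel


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_ising():
    """A fixed N=5 pairwise model with moderate biases and couplings."""
    gen = np.random.default_rng(42)
    h = gen.uniform(-3, -1, 5)
    J = np.zeros((5, 5))
    iu, ju = np.triu_indices(5, k=1)
    J[iu, ju] = gen.uniform(-0.5, 0.5, len(iu))
    J = J + J.T
    return MaxEntModel.from_params(h, J)


@pytest.fixture(scope="session")
def independent_model():
    """N=5 independent model with heterogeneous marginals."""
    q = np.array([0.02, 0.05, 0.1, 0.2, 0.3])
    return MaxEntModel.from_params(np.log(q / (1 - q)))
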