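import numpy as np
import pytest

from mr2dnm.dnm import DNMArchitecture, DNMParameters


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_arch():
    return DNMArchitecture(n_features=3, n_branches=4, k=3.0, k_soma=10.0, theta_soma=0.5)


@pytest.fixture
def random_params(rng, small_arch):
    shape = (small_arch.n_features, small_arch.n_branches)
    return DNMParameters(rng.uniform(-1.5, 1.5, shape), rng.uniform(-1.5, 1.5, shape))


@pytest.fixture
def bupa_shaped_arch():
    # 5 selected features on 10 branches: 50 synaptic / 10 dendritic points
    return DNMArchitecture(n_features=5, n_branches=10, k=3.0, k_soma=10.0, theta_soma=0.5)
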