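import numpy as np
import pytest

from dmreg import AnglePairs, DMParams, predict


@pytest.fixture
def rng():
    return np.random.default_rng(20160411)


@pytest.fixture
def exact_params():
    # on the default initialization lattice: pi/2 = -pi + 90*(pi/60), omega on 0.05 grid
    return DMParams(alpha=np.pi / 2, beta=np.pi / 2, omega=0.5)


def make_noise_free(params: DMParams, n: int, seed: int = 0) -> AnglePairs:
    """Pairs lying exactly on the regression curve."""
    rng = np.random.default_rng(seed)
    u = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return AnglePairs(u, predict(u, params))


@pytest.fixture
def noise_free_data(exact_params):
    return make_noise_free(exact_params, n=50, seed=1)
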