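import numpy as np
import pytest

import metpredict as mp
from metpredict.datatypes import VarianceParams


@pytest.fixture(scope="session")
def tiny():
    """One small simulated study reused across read-only tests."""
    return mp.tiny_scenario(11, n_sc=1, gamma="kinship")


@pytest.fixture(scope="session")
def tiny_means(tiny):
    """Stage II-level means for the tiny scenario (heterogeneous weights)."""
    rng = np.random.default_rng(5)
    M, I = tiny.truth.true_means.shape
    rv = 0.004 * (1.0 + rng.random((M, I)))
    return mp.simulate_stacked_means(tiny.truth, residual_var=rv, seed=17)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def identity_vparams(sigma2_a=0.04, sigma2_l=0.09, sigma2_s=0.02, n_sc=0,
                     sigma2_b=0.01):
    G = np.zeros((1 + n_sc, 1 + n_sc))
    G[0, 0] = sigma2_a
    for k in range(n_sc):
        G[1 + k, 1 + k] = sigma2_b
    return VarianceParams(g_matrix=G, sigma2_l=sigma2_l, sigma2_s=sigma2_s)
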