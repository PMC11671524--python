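import numpy as np
import pytest
from hypothesis import settings

from markovcea import load_gbc_fixture

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def bundle():
    return load_gbc_fixture()


@pytest.fixture(scope="session")
def gbc_config(bundle):
    return bundle.config


def brute_force_trace(P, horizon, init=0):
    """Independent cohort-trace oracle: plain Python loops, no numpy
    matrix products, used to cross-check the engine's occupancy."""
    n = len(P)
    occ = [[0.0] * n for _ in range(horizon + 1)]
    occ[0][init] = 1.0
    for t in range(1, horizon + 1):
        for j in range(n):
            occ[t][j] = sum(occ[t - 1][i] * P[i][j] for i in range(n))
    return np.array(occ)
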