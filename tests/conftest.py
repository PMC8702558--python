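import numpy as np
import pytest

import tsnet


@pytest.fixture(scope="session")
def params():
    return tsnet.ModelParams()


@pytest.fixture(scope="session")
def trained_k1m3(params):
    """One K=1, M=3 network trained at defaults, shared across tests."""
    rng = np.random.default_rng(np.random.SeedSequence(2024))
    task = tsnet.make_simple_task(params.N, 1, 3, rng)
    conn = tsnet.init_connectivity(params, rng)
    net = tsnet.train_sequences(conn, task, params, rng=rng)
    return net, task, rng


@pytest.fixture()
def tiny_setup():
    """Small deterministic network for cheap dynamical checks (N=6)."""
    params = tsnet.ModelParams(N=6, rho=0.25)
    rng = np.random.default_rng(7)
    conn = tsnet.init_connectivity(params, rng)
    state = tsnet.NetworkState(rng.uniform(-1, 1, 6), rng.uniform(-1, 1, 6))
    eta = 2.0 * rng.integers(0, 2, 6) - 1.0
    return params, conn, state, eta
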