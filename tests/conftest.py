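import logging

import numpy as np
import pytest

from spanmrf import nb_mixture as nbm
from spanmrf.graph import NeighborGraph
from spanmrf.simulate import SimConfig, marker_view, simulate_dataset

logging.getLogger("spanmrf").setLevel(logging.ERROR)


def graph_from_edges(n, edges):
    adj = [set() for _ in range(n)]
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    return NeighborGraph(n_spots=n, adjacency=adj)


@pytest.fixture
def path3():
    """Path graph 0-1-2."""
    return graph_from_edges(3, [(0, 1), (1, 2)])


def random_mixture_instance(rng, N, G, K, P=0, B=3):
    """A small, fully random but valid mixture problem."""
    Y = rng.poisson(3.0, size=(N, G))
    rho = (rng.random((G, K)) < 0.5).astype(float)
    rho[rho.sum(axis=1) == 0, 0] = 1.0
    for k in np.flatnonzero(rho.sum(axis=0) == 0):
        rho[rng.integers(G), k] = 1.0
    hyper = nbm.HyperParams(B=B)
    params = nbm.init_params(Y, rho, P, hyper, rng)
    params.delta_raw = rng.normal(0.3, 0.3, size=(G, K))
    params.beta0 = rng.normal(0.5, 0.5, size=G)
    params.a_raw = rng.normal(0.5, 0.3, size=B)
    params.b_raw = rng.normal(-1.0, 0.3, size=B)
    params.pi_raw = rng.normal(0.0, 0.5, size=K)
    if P:
        params.beta = rng.normal(0.0, 0.3, size=(G, P))
    X = rng.normal(0.0, 1.0, size=(N, P)) if P else None
    s = np.exp(rng.normal(0.0, 0.2, size=N))
    return Y, rho, X, s, params, hyper


@pytest.fixture(scope="session")
def strong_signal_dataset():
    """Well-separated three-type dataset on a 15x15 grid."""
    ds = simulate_dataset(SimConfig(n_spots=225, n_genes=600, K=3, sigma=0.6, seed=11))
    Y, rho = marker_view(ds)
    return ds, Y, rho
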