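"""Shared fixtures: tiny parcellations and toy connectomes."""

import numpy as np
import pandas as pd
import pytest

from curvnet.io import Connectome, Parcellation
from curvnet.synth import generate_parcellation


def make_parcellation(n: int) -> Parcellation:
    """Deterministic n-node parcellation for toy graphs."""
    return generate_parcellation(n, seed=12345)


def make_connectome(weights) -> Connectome:
    W = np.asarray(weights, dtype=float)
    return Connectome.from_array(make_parcellation(W.shape[0]), W)


def cycle_weights(n: int) -> np.ndarray:
    W = np.zeros((n, n))
    for i in range(n):
        W[i, (i + 1) % n] = W[(i + 1) % n, i] = 1.0
    return W


def random_connected_weights(rng: np.random.Generator, n: int,
                             p: float = 0.6) -> np.ndarray:
    """Random connected weighted graph: spanning path + extra edges."""
    W = np.zeros((n, n))
    order = rng.permutation(n)
    for a, b in zip(order[:-1], order[1:]):
        W[a, b] = W[b, a] = rng.uniform(0.2, 3.0)
    iu, ju = np.triu_indices(n, 1)
    extra = rng.random(iu.size) < p
    for i, j in zip(iu[extra], ju[extra]):
        if W[i, j] == 0:
            W[i, j] = W[j, i] = rng.uniform(0.2, 3.0)
    return W


@pytest.fixture
def parc3():
    return make_parcellation(3)


@pytest.fixture
def triangle():
    """Unit-weight complete triangle."""
    return make_connectome(1.0 - np.eye(3))


@pytest.fixture
def path3():
    """Unit-weight path 0-1-2."""
    return make_connectome([[0, 1, 0], [1, 0, 1], [0, 1, 0]])


@pytest.fixture
def hexagon():
    """Unit-weight 6-cycle."""
    return make_connectome(cycle_weights(6))
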