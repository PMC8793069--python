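import numpy as np
import pytest

from walkboost import InteractionNetwork, SyntheticSpec, generate_planted_module


@pytest.fixture
def k2_network() -> InteractionNetwork:
    """Two genes joined by one edge — the smallest diffusable network."""
    return InteractionNetwork(
        genes=["A", "B"],
        adjacency=np.array([[0.0, 1.0], [1.0, 0.0]]),
        seed_flags=np.array([True, False]),
    )


@pytest.fixture
def path3_network() -> InteractionNetwork:
    """Path graph A - B - C."""
    adj = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
    return InteractionNetwork(
        genes=["A", "B", "C"], adjacency=adj, seed_flags=np.array([True, False, False])
    )


@pytest.fixture(scope="session")
def small_planted_network():
    """Small planted-module network shared across tests (deterministic)."""
    spec = SyntheticSpec(n_disease=20, n_background=80, seed=7)
    return generate_planted_module(spec)


def random_column_stochastic(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random symmetric-support weighted graph, column-normalized."""
    A = rng.random((n, n)) * (rng.random((n, n)) < 0.3)
    A = np.triu(A, k=1)
    A = A + A.T
    # guarantee no isolated column
    for i in range(n):
        if A[:, i].sum() == 0:
            j = (i + 1) % n
            A[i, j] = A[j, i] = 1.0
    return A / A.sum(axis=0)
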