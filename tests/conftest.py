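import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from connrepro import BinaryGraph, ConnectivityMatrix


def random_adjacency(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    """Erdős–Rényi-style symmetric binary adjacency with zero diagonal."""
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, k=1)
    return (adj | adj.T).astype(np.int8)


def random_weights(rng: np.random.Generator, n: int, p: float = 0.6) -> np.ndarray:
    """Random symmetric nonnegative weight matrix with zero diagonal."""
    w = rng.integers(1, 100, size=(n, n)).astype(float)
    mask = np.triu(rng.random((n, n)) < p, k=1)
    w = np.where(mask, w, 0.0)
    return w + w.T


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)


def graph_from_edges(n: int, edges: list[tuple[int, int]]) -> BinaryGraph:
    adj = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    return BinaryGraph(adjacency=adj)


def matrix_from_weights(w: np.ndarray, **ids) -> ConnectivityMatrix:
    return ConnectivityMatrix(weights=np.asarray(w, dtype=float), **ids)
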