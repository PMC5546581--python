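"""Shared fixtures and independent oracles for the walkscreen test suite.

The oracles here deliberately avoid the package's own code paths: dense
matrices are built by brute-force iteration over raw edge lists, and the
restart-walk fixed point is obtained by a closed-form linear solve rather
than by iteration.
"""

from __future__ import annotations

import numpy as np
import pytest

from walkscreen.network import (
    InteractionRecord,
    PPINetwork,
    build_transition_matrix,
)


def make_network(edges, extra_nodes=()):
    """Build a PPINetwork from (a, b, score) triples."""
    return PPINetwork(
        [InteractionRecord(a, b, s) for a, b, s in edges], extra_nodes=extra_nodes
    )


def dense_adjacency(network: PPINetwork) -> np.ndarray:
    """Brute-force dense symmetric adjacency from the raw edge dict."""
    n = len(network)
    A = np.zeros((n, n))
    for (a, b), s in network.edges.items():
        i, j = network.node_index[a], network.node_index[b]
        A[i, j] = A[j, i] = s
    return A


def dense_transition(network: PPINetwork) -> np.ndarray:
    """Column-normalize the dense adjacency; zero columns stay zero."""
    A = dense_adjacency(network)
    colsum = A.sum(axis=0)
    T = np.zeros_like(A)
    nz = colsum > 0
    T[:, nz] = A[:, nz] / colsum[nz]
    return T


def rwr_linear_solve(network: PPINetwork, p0: np.ndarray, c: float) -> np.ndarray:
    """Closed-form restart-walk fixed point.

    Solves p = (1-c) (T p + m p0) + c p0 where m is the mass sitting on
    dangling columns, i.e. (I - (1-c)(T + p0 d^T)) p = c p0.
    """
    T = dense_transition(network)
    dangling = (T.sum(axis=0) == 0).astype(float)
    M = (1.0 - c) * (T + np.outer(p0, dangling))
    return np.linalg.solve(np.eye(len(network)) - M, c * p0)


def random_network(rng: np.random.Generator, n_max: int = 50) -> PPINetwork:
    """A random weighted graph with <= n_max nodes, possibly with isolated
    nodes; scores drawn from (0, 1000]."""
    n = int(rng.integers(3, n_max + 1))
    names = [f"G{i:03d}" for i in range(n)]
    p_edge = float(rng.uniform(0.05, 0.4))
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                edges.append((names[i], names[j], int(rng.integers(1, 1001))))
    if not edges:  # force at least one edge so the walk has somewhere to go
        edges.append((names[0], names[1], int(rng.integers(1, 1001))))
    return make_network(edges, extra_nodes=names)


@pytest.fixture
def path_network():
    """A -- B -- C with equal scores; the worked RWR example."""
    return make_network([("A", "B", 500), ("B", "C", 500)])


@pytest.fixture
def star_network():
    """Hub A with unequal spokes: S(A,B)=900, S(A,C)=100."""
    return make_network([("A", "B", 900), ("A", "C", 100)])


@pytest.fixture
def path_transition(path_network):
    return build_transition_matrix(path_network)
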