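"""Shared fixtures and the independent Lyapunov covariance oracle.

The oracle never touches the spectral edge-importance code path: it builds
``L`` and ``B`` directly from the edge list, restricts to the zero-sum
subspace (orthogonal complement of the all-ones vector, which ``L`` leaves
invariant), and solves the continuous Lyapunov equation
``L C + C L^T + B B^T = 0`` there.
"""

import numpy as np
import pytest
from scipy.linalg import null_space, solve_continuous_lyapunov

from stochshield.graph_core import Edge, MeasurementVector, ReactionGraph


@pytest.fixture
def threestate():
    """3-state chain with unit rates/noise and M = [0, 0, 1]."""
    edges = (Edge(0, 1, 1.0), Edge(1, 0, 1.0), Edge(1, 2, 1.0), Edge(2, 1, 1.0))
    return ReactionGraph(3, edges), MeasurementVector(np.array([0.0, 0.0, 1.0]))


@pytest.fixture
def two_state():
    return ReactionGraph(2, (Edge(0, 1, 1.0), Edge(1, 0, 1.0)))


def dense_laplacian(graph: ReactionGraph) -> np.ndarray:
    n = graph.n_nodes
    A = np.zeros((n, n))
    for e in graph.edges:
        A[e.source, e.target] += e.rate
    return (A - np.diag(A.sum(axis=1))).T


def noise_columns(graph: ReactionGraph) -> np.ndarray:
    n, m = graph.n_nodes, graph.n_edges
    B = np.zeros((n, m))
    for k, e in enumerate(graph.edges):
        B[e.source, k] = -e.sigma
        B[e.target, k] = e.sigma
    return B


def lyapunov_covariance(graph: ReactionGraph, columns=None) -> np.ndarray:
    """Stationary covariance of dX = LX dt + B dW by direct Lyapunov solve.

    ``columns`` restricts B to a subset of noise columns (for the deficiency
    process, whose effective noise matrix is B with only the neglected
    columns kept).
    """
    L = dense_laplacian(graph)
    B = noise_columns(graph)
    if columns is not None:
        mask = np.zeros(B.shape[1], dtype=bool)
        mask[list(columns)] = True
        B = B[:, mask]
    n = L.shape[0]
    U = null_space(np.ones((1, n)))
    Lt = U.T @ L @ U
    Q = U.T @ B
    C = solve_continuous_lyapunov(Lt, -Q @ Q.T)
    return U @ C @ U.T


def lyapunov_readout_variance(graph, M, columns=None) -> float:
    m = M.values if isinstance(M, MeasurementVector) else np.asarray(M, float)
    C = lyapunov_covariance(graph, columns)
    return float(m @ C @ m)


def random_connected_er(rng, n_lo=3, n_hi=12, p=0.5, random_sigma=True):
    """Small connected bidirectional ER reaction graph for oracle tests."""
    from stochshield.ensemble import sample_er_graph

    while True:
        n = int(rng.integers(n_lo, n_hi + 1))
        graph = sample_er_graph(n, p, rng)
        if graph.n_edges > 0:
            break
    if random_sigma:
        graph = graph.with_sigmas(rng.uniform(0.5, 2.0, size=graph.n_edges))
    return graph


def random_binary_measurement(rng, n) -> MeasurementVector:
    n1 = int(rng.integers(1, n))  # non-constant: at least one 0 and one 1
    M = np.zeros(n)
    M[rng.choice(n, n1, replace=False)] = 1.0
    return MeasurementVector(M)
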