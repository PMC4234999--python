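"""Reaction graphs, graph Laplacians and their spectral decompositions.

A first-order (monomolecular) reaction network is a directed weighted graph:
nodes are states, and each directed edge ``k`` carries a per-capita rate
``alpha_k > 0`` and a dimensionless noise scale ``sigma_k >= 0``.  The mean
dynamics of the occupancy vector are generated by the graph Laplacian
``L = (A - D)^T`` where ``A`` is the weighted adjacency matrix and ``D`` the
diagonal matrix of weighted out-degrees.  Columns of ``L`` sum to zero, so the
total occupancy is conserved.

Node indices are 0-based internally; file I/O and the CLI use 1-based indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Edge",
    "ReactionGraph",
    "GraphLaplacian",
    "SpectralData",
    "MeasurementVector",
    "ReducibleGraphError",
    "build_laplacian",
    "stoichiometry",
    "stoichiometry_matrix",
    "spectral_decomposition",
    "stationary_distribution",
    "connected_components",
]

#: relative tolerance used to identify the zero eigenvalue of a Laplacian
_ZERO_EIG_RTOL = 1e-9
#: maximum condition number of the right-eigenvector matrix before the
#: Laplacian is treated as (numerically) defective
_MAX_EIGVEC_COND = 1e8


class ReducibleGraphError(ValueError):
    """Raised when an operation requires an irreducible (weakly connected)
    graph but the zero eigenvalue of the Laplacian is not simple.  Callers
    should fall back to per-component evaluation (see
    :func:`stochshield.edge_importance.per_component_importance`)."""


class Edge(NamedTuple):
    """Directed reaction ``source -> target`` with rate ``alpha`` (per unit
    time) and noise scale ``sigma`` (multiplier on the Wiener increment)."""

    source: int
    target: int
    rate: float
    sigma: float = 1.0


@dataclass(frozen=True)
class ReactionGraph:
    """Directed weighted reaction network.

    Parameters
    ----------
    n_nodes
        Number of states.
    edges
        Ordered sequence of edges; the position of an edge in this sequence is
        the canonical reaction index ``k`` used by every downstream operation.
    labels
        Optional node labels (purely cosmetic).
    """

    n_nodes: int
    edges: tuple[Edge, ...]
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be a positive integer")
        edges = tuple(Edge(*e) for e in self.edges)
        object.__setattr__(self, "edges", edges)
        for k, e in enumerate(edges):
            if not (0 <= e.source < self.n_nodes and 0 <= e.target < self.n_nodes):
                raise ValueError(
                    f"edge {k}: node index out of range for n_nodes={self.n_nodes}"
                )
            if e.source == e.target:
                raise ValueError(f"edge {k}: self-loops are not allowed")
            if not e.rate > 0:
                raise ValueError(f"edge {k}: rate must be strictly positive")
            if e.sigma < 0:
                raise ValueError(f"edge {k}: sigma must be nonnegative")
        if self.labels is not None and len(self.labels) != self.n_nodes:
            raise ValueError("labels must have one entry per node")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def rates(self) -> np.ndarray:
        return np.array([e.rate for e in self.edges], dtype=float)

    def sigmas(self) -> np.ndarray:
        return np.array([e.sigma for e in self.edges], dtype=float)

    def with_sigmas(self, sigmas: Sequence[float]) -> "ReactionGraph":
        """Return a copy with the noise scales replaced."""
        if len(sigmas) != self.n_edges:
            raise ValueError("need one sigma per edge")
        new = tuple(
            Edge(e.source, e.target, e.rate, float(s))
            for e, s in zip(self.edges, sigmas)
        )
        return ReactionGraph(self.n_nodes, new, self.labels)


@dataclass(frozen=True)
class GraphLaplacian:
    """Graph Laplacian ``L = (A - D)^T`` together with its building blocks."""

    matrix: np.ndarray
    adjacency: np.ndarray
    out_degree: np.ndarray
    symmetric: bool

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class SpectralData:
    """Eigen-decomposition of a graph Laplacian.

    Eigenvalues are sorted by decreasing real part, so the zero eigenvalue of
    an irreducible Laplacian sits at index 0.  ``right[:, i]`` is the right
    eigenvector ``v_i`` (unit 2-norm, first nonzero component positive);
    ``left[i, :]`` is the left eigenvector ``w_i^T`` normalised so that
    ``w_i^T v_j = delta_ij``.  In the symmetric case ``left == right.T`` and
    the system is orthonormal.
    """

    eigenvalues: np.ndarray
    right: np.ndarray
    left: np.ndarray
    symmetric: bool
    zero_index: int = 0

    @property
    def n(self) -> int:
        return self.right.shape[0]

    def reconstruct(self) -> np.ndarray:
        """Return ``sum_i lambda_i v_i w_i^T`` (should equal ``L``)."""
        lam = self.eigenvalues
        out = (self.right * lam) @ self.left
        return np.real_if_close(out, tol=1000)

    @property
    def zero_multiplicity(self) -> int:
        lam = self.eigenvalues
        scale = max(np.abs(lam).max(), 1.0)
        return int(np.sum(np.abs(lam) < _ZERO_EIG_RTOL * scale))


@dataclass(frozen=True)
class MeasurementVector:
    """Linear measurement functional ``M``: one value per node.

    ``mode`` is ``"binary"`` ({0,1} entries, e.g. conducting / non-conducting)
    or ``"graded"`` (entries in [0, 1]).
    """

    values: np.ndarray
    mode: str = "binary"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1:
            raise ValueError("measurement vector must be one-dimensional")
        if self.mode == "binary":
            if not np.all(np.isin(v, (0.0, 1.0))):
                raise ValueError("binary measurement entries must be 0 or 1")
        elif self.mode == "graded":
            if np.any(v < 0) or np.any(v > 1):
                raise ValueError("graded measurement entries must lie in [0, 1]")
        else:
            raise ValueError(f"unknown measurement mode {self.mode!r}")

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "MeasurementVector":
        v = np.asarray(values, dtype=float)
        mode = "binary" if np.all(np.isin(v, (0.0, 1.0))) else "graded"
        return cls(v, mode)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.values)


def build_laplacian(graph: ReactionGraph, merge_parallel: bool = False) -> GraphLaplacian:
    """Assemble ``L = (A - D)^T`` from a reaction graph.

    ``A[i, j]`` is the rate of the edge ``i -> j``; ``D`` is the diagonal of
    weighted out-degrees.  Parallel directed edges are rejected unless
    ``merge_parallel`` is set, in which case their rates are summed (the
    reaction index would otherwise be ambiguous downstream).
    """
    n = graph.n_nodes
    A = np.zeros((n, n))
    seen: set[tuple[int, int]] = set()
    for k, e in enumerate(graph.edges):
        key = (e.source, e.target)
        if key in seen and not merge_parallel:
            raise ValueError(
                f"edge {k}: duplicate directed edge {e.source}->{e.target}; "
                "pass merge_parallel=True to sum rates"
            )
        seen.add(key)
        A[e.source, e.target] += e.rate
    D = np.diag(A.sum(axis=1))
    L = (A - D).T
    symmetric = bool(np.allclose(A, A.T, rtol=1e-12, atol=1e-14 * max(A.max(), 1.0)))
    return GraphLaplacian(matrix=L, adjacency=A, out_degree=np.diag(D), symmetric=symmetric)


def stoichiometry(graph: ReactionGraph, k: int) -> np.ndarray:
    """Stoichiometry vector ``zeta_k``: -1 at the source node of edge ``k``,
    +1 at its target, zero elsewhere."""
    if not 0 <= k < graph.n_edges:
        raise IndexError(f"edge index {k} out of range (m={graph.n_edges})")
    z = np.zeros(graph.n_nodes)
    e = graph.edges[k]
    z[e.source] = -1.0
    z[e.target] = 1.0
    return z


def stoichiometry_matrix(graph: ReactionGraph) -> np.ndarray:
    """All stoichiometry vectors as columns of an ``n x m`` matrix."""
    Z = np.zeros((graph.n_nodes, graph.n_edges))
    for k, e in enumerate(graph.edges):
        Z[e.source, k] = -1.0
        Z[e.target, k] = 1.0
    return Z


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: first nonzero component of each column
    positive.  (Edge importance is invariant under sign flips; a fixed
    convention just makes results reproducible.)"""
    V = V.copy()
    for i in range(V.shape[1]):
        col = V[:, i]
        nz = np.flatnonzero(np.abs(col) > 1e-12 * max(np.abs(col).max(), 1e-300))
        if nz.size:
            lead = col[nz[0]]
            s = lead.real if abs(lead.real) > 1e-12 * abs(lead) else lead.imag
            if s < 0:
                V[:, i] = -col
    return V


def spectral_decomposition(lap: GraphLaplacian | np.ndarray) -> SpectralData:
    """Eigen-decomposition of a graph Laplacian.

    Symmetric Laplacians go through the real symmetric solver (orthonormal
    eigenvectors, ``left = right.T``).  Non-symmetric ones use the general
    solver; the left eigenvectors are the rows of the inverse right-eigenvector
    matrix, which enforces biorthogonality ``w_i^T v_j = delta_ij``.  Raises if
    the eigenvector matrix is too ill-conditioned (near-defective Laplacian)
    or if an eigenvalue has a positive real part beyond tolerance.
    """
    if isinstance(lap, GraphLaplacian):
        L = lap.matrix
        symmetric = lap.symmetric
    else:
        L = np.asarray(lap, dtype=float)
        symmetric = bool(np.allclose(L, L.T))

    n = L.shape[0]
    if symmetric:
        lam, V = np.linalg.eigh(L)
        order = np.argsort(-lam)
        lam, V = lam[order], V[:, order]
        V = _fix_signs(V)
        W = V.T.copy()
        lam = lam.astype(float)
    else:
        lam, V = np.linalg.eig(L)
        order = np.lexsort((-lam.imag, -lam.real))
        lam, V = lam[order], V[:, order]
        V = V / np.linalg.norm(V, axis=0, keepdims=True)
        cond = np.linalg.cond(V)
        if cond > _MAX_EIGVEC_COND:
            gaps = np.abs(np.subtract.outer(lam, lam)) + np.eye(n)
            i, j = np.unravel_index(np.argmin(gaps), gaps.shape)
            raise np.linalg.LinAlgError(
                f"Laplacian is numerically defective (eigenvector condition "
                f"number {cond:.2e}); closest eigenvalue cluster: "
                f"lambda_{i + 1}={lam[i]:.6g}, lambda_{j + 1}={lam[j]:.6g}"
            )
        V = _fix_signs(V)
        W = np.linalg.inv(V)
        if np.allclose(lam.imag, 0.0, atol=1e-12 * max(np.abs(lam).max(), 1.0)):
            lam = lam.real
            V = V.real.copy() if np.allclose(V.imag, 0) else V
            W = W.real.copy() if np.allclose(W.imag, 0) else W

    scale = max(np.abs(lam).max(), 1.0)
    if np.real(lam[0]) > _ZERO_EIG_RTOL * scale:
        raise ValueError(
            f"eigenvalue with positive real part ({lam[0]:.3e}): not a valid "
            "graph Laplacian"
        )
    if abs(lam[0]) > _ZERO_EIG_RTOL * scale:
        raise ValueError(
            f"leading eigenvalue {lam[0]:.3e} is not zero within tolerance; "
            "not a valid graph Laplacian"
        )
    return SpectralData(eigenvalues=lam, right=V, left=W, symmetric=symmetric)


def stationary_distribution(spec: SpectralData) -> np.ndarray:
    """Stationary distribution ``pi``: the right null vector of ``L``
    normalised to sum to one.

    Requires an irreducible graph (simple zero eigenvalue); negative entries
    below 1e-12 are clipped to zero and the vector renormalised.
    """
    if spec.zero_multiplicity > 1:
        raise ReducibleGraphError(
            "zero eigenvalue is not simple: graph is reducible; use "
            "connected_components and evaluate per component"
        )
    v = np.real(spec.right[:, spec.zero_index])
    if v.sum() < 0:
        v = -v
    if np.any(v < -1e-12 * max(np.abs(v).max(), 1e-300) * spec.n):
        raise ValueError("zero eigenvector has significant negative entries")
    v = np.clip(v, 0.0, None)
    return v / v.sum()


def connected_components(graph: ReactionGraph) -> list[list[int]]:
    """Weakly connected components, each a sorted list of node indices.

    Components are ordered by their smallest node index.  Isolated nodes form
    singleton components.
    """
    g = nx.Graph()
    g.add_nodes_from(range(graph.n_nodes))
    g.add_edges_from((e.source, e.target) for e in graph.edges)
    comps = [sorted(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: c[0])
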