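"""Erdos-Renyi random-graph ensemble diagnostics.

For a symmetric Erdos-Renyi reaction graph G(n, p) — each of the (n^2-n)/2
node pairs carries a bidirectional unit-rate edge independently with
probability p — the edge-importance spectrum splits into two classes set by a
binary measurement vector M: edges joining differently labelled nodes
("type 0-1", important) concentrate near 1/(nC) with C = 2p, while edges
joining identically labelled nodes sink below the fourth-moment scale of the
Laplacian eigenvector components (~ 2 n^{-5/3} empirically).  This module
samples the ensemble, estimates the eigenvector moment scalings, the
eigenvalue-sum statistic S and its 1/(2pn) limit, the R_k clustering, the
graded-measurement quadratic law, and the connectivity bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .edge_importance import edge_importance
from .graph_core import (
    Edge,
    MeasurementVector,
    ReactionGraph,
    build_laplacian,
    connected_components,
    spectral_decomposition,
)

__all__ = [
    "EnsembleSpec",
    "MomentEstimates",
    "ClusteringSample",
    "ClusteringResult",
    "GradedResult",
    "sample_er_graph",
    "er_laplacian",
    "moment_diagnostics",
    "fit_moment_exponent",
    "mean_S",
    "rk_clustering",
    "graded_measurement_experiment",
    "connectivity_bound",
]


@dataclass(frozen=True)
class EnsembleSpec:
    """Parameters of one ensemble experiment.

    ``measurement`` is ``"binary"`` (``n1`` nodes labelled 1, chosen uniformly
    at random, independent of the edges) or ``"graded"`` (labels uniform on
    [0, 1]).  ``C = 2p`` is the constant in the important-class limit 1/(nC).
    """

    n: int
    p: float
    reps: int = 100
    seed: int = 0
    measurement: str = "binary"
    n1: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.p < 1:
            raise ValueError("edge probability p must lie in (0, 1)")
        if self.measurement == "binary":
            n1 = self.n // 2 if self.n1 is None else self.n1
            if not 0 < n1 < self.n:
                raise ValueError("binary measurement needs 0 < n1 < n")
            object.__setattr__(self, "n1", n1)
        elif self.measurement != "graded":
            raise ValueError("measurement must be 'binary' or 'graded'")

    @property
    def C(self) -> float:
        return 2.0 * self.p


def sample_er_graph(
    n: int,
    p: float,
    rng: np.random.Generator,
    require_connected: bool = True,
    max_tries: int = 1000,
) -> ReactionGraph:
    """Draw a symmetric Erdos-Renyi reaction graph.

    Each included undirected pair (i, j), i < j, contributes the two directed
    edges i->j and j->i with unit rate and unit noise scale, in lexicographic
    pair order (forward edge first).  Disconnected samples are redrawn by
    default (probability <= n^2/2 (1-p)^(n-1), astronomically small at the
    parameter values of interest).
    """
    iu, ju = np.triu_indices(n, k=1)
    for _ in range(max_tries):
        mask = rng.random(iu.size) < p
        edges = []
        for i, j in zip(iu[mask], ju[mask]):
            edges.append(Edge(int(i), int(j), 1.0, 1.0))
            edges.append(Edge(int(j), int(i), 1.0, 1.0))
        graph = ReactionGraph(n, tuple(edges))
        if not require_connected or len(connected_components(graph)) == 1:
            return graph
    raise RuntimeError("failed to draw a connected sample")


def er_laplacian(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    """Laplacian of an ER sample without the graph object (moment/S sweeps).

    Connectivity is not enforced here; callers that need a simple zero
    eigenvalue should check (a disconnected sample shows up as a repeated
    zero eigenvalue and is excluded with a log by the sweep drivers).
    """
    iu, ju = np.triu_indices(n, k=1)
    A = np.zeros((n, n))
    mask = rng.random(iu.size) < p
    A[iu[mask], ju[mask]] = 1.0
    A[ju[mask], iu[mask]] = 1.0
    return (A - np.diag(A.sum(axis=1))).T  # symmetric: transpose is cosmetic


@dataclass(frozen=True)
class MomentEstimates:
    """Eigenvector-component moment estimates per graph size.

    All quantities average over the non-null eigenvectors (i >= 2), all
    component indices, and ``reps`` independent samples, with the sign of
    each eigenvector randomised (+/- with probability 1/2) so odd moments are
    unbiased.  Keys of every mapping are the graph sizes ``n``.
    """

    ns: tuple[int, ...]
    p: float
    reps: int
    mean_v: dict[int, float]  # E[v_i(l)]
    m4: dict[int, float]  # E[v_i(l)^4]
    m22: dict[int, float]  # E[v_i(l)^2 v_i(l')^2], l != l'
    m11_same: dict[int, float]  # E[v_i(l) v_i(l')], l != l'
    m11_cross: dict[int, float]  # E[v_i(l) v_j(l')], i != j
    m211: dict[int, float]  # E[v_i(l1)^2 v_i(l2) v_i(l3)], distinct
    m1111: dict[int, float]  # E[v_i(l1) v_i(l2) v_i(l3) v_i(l4)], distinct


def moment_diagnostics(
    ns: Sequence[int], p: float = 0.5, reps: int = 100, seed: int = 0
) -> MomentEstimates:
    """Estimate the eigenvector moment scalings on a grid of graph sizes.

    The per-eigenvector averages over distinct component tuples are computed
    exactly from power sums (p_r = sum_l v(l)^r), so a single eigenvector
    contributes its full average over all index combinations.
    """
    if reps < 100:
        raise ValueError("moment diagnostics require reps >= 100")
    rng = np.random.default_rng(seed)
    out = {key: {} for key in ("mean_v", "m4", "m22", "m11_same", "m11_cross", "m211", "m1111")}
    for n in ns:
        acc = {key: 0.0 for key in out}
        count = 0
        for _ in range(reps):
            L = er_laplacian(n, p, rng)
            lam, V = np.linalg.eigh(L)
            order = np.argsort(-lam)
            V = V[:, order][:, 1:]  # non-null eigenvectors
            signs = rng.choice((-1.0, 1.0), size=V.shape[1])
            V = V * signs
            p1 = V.sum(axis=0)
            p2 = (V**2).sum(axis=0)  # == 1
            p3 = (V**3).sum(axis=0)
            p4 = (V**4).sum(axis=0)
            nn = float(n)
            acc["mean_v"] += (p1 / nn).mean()
            acc["m4"] += (p4 / nn).mean()
            acc["m22"] += ((p2**2 - p4) / (nn * (nn - 1))).mean()
            acc["m11_same"] += ((p1**2 - p2) / (nn * (nn - 1))).mean()
            # cross term: average over ordered eigenvector pairs i != j
            P = p1.sum()
            npairs = p1.size * (p1.size - 1)
            acc["m11_cross"] += ((P**2 - (p1**2).sum()) / npairs / nn**2) if npairs else 0.0
            t211 = p2 * p1**2 - 2 * p3 * p1 - p2**2 + 2 * p4
            acc["m211"] += (t211 / (nn * (nn - 1) * (nn - 2))).mean()
            t1111 = p1**4 - 6 * p1**2 * p2 + 3 * p2**2 + 8 * p1 * p3 - 6 * p4
            acc["m1111"] += (t1111 / (nn * (nn - 1) * (nn - 2) * (nn - 3))).mean()
            count += 1
        for key in out:
            out[key][n] = acc[key] / count
    return MomentEstimates(ns=tuple(ns), p=p, reps=reps, **out)


def fit_moment_exponent(estimates: MomentEstimates) -> tuple[float, float]:
    """Least-squares exponent of the fourth-moment scaling E[v^4] ~ c n^{-q}.

    Returns ``(q, se)``: the negated slope of log E[v^4] against log n and
    its standard error.  Requires at least four sizes spanning a decade.
    """
    ns = np.array(estimates.ns, dtype=float)
    if ns.size < 4 or ns.max() / ns.min() < 10:
        raise ValueError("need >= 4 graph sizes spanning at least a decade")
    y = np.log(np.array([estimates.m4[int(n)] for n in ns]))
    x = np.log(ns)
    A = np.vstack([x, np.ones_like(x)]).T
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    dof = ns.size - 2
    s2 = float(res[0]) / dof if res.size else 0.0
    se = float(np.sqrt(s2 * np.linalg.inv(A.T @ A)[0, 0]))
    return -float(coef[0]), se


def mean_S(
    ns: Sequence[int],
    ps: Sequence[float],
    reps: int = 10,
    seed: int = 0,
) -> dict[tuple[int, float], dict[str, float]]:
    """Sample mean and SD of S = (n-1)^{-2} sum_{i,j>=2} -1/(lambda_i+lambda_j)
    on an (n, p) grid, with the large-n reference 1/(2pn).

    Disconnected samples (repeated zero eigenvalue) are excluded and logged.
    """
    rng = np.random.default_rng(seed)
    out: dict[tuple[int, float], dict[str, float]] = {}
    for n in ns:
        for p in ps:
            vals = []
            dropped = 0
            while len(vals) < reps:
                L = er_laplacian(n, p, rng)
                lam = np.linalg.eigvalsh(L)
                lam = np.sort(lam)[::-1]
                if abs(lam[1]) < 1e-9 * max(abs(lam).max(), 1.0):
                    dropped += 1
                    if dropped > 100 * reps:
                        raise RuntimeError("too many disconnected samples")
                    continue
                nz = lam[1:]
                S = (-1.0 / (nz[:, None] + nz[None, :])).sum() / (n - 1) ** 2
                vals.append(S)
            vals = np.asarray(vals)
            out[(n, p)] = {
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if reps > 1 else 0.0,
                "reference": 1.0 / (2 * p * n),
                "dropped": float(dropped),
            }
    return out


@dataclass(frozen=True)
class ClusteringSample:
    """Edge-importance clustering of a single ER sample."""

    R_sorted: np.ndarray = field(repr=False)
    important_mean: float
    unimportant_mean: float
    unimportant_max: float
    important_min: float
    gap: float  # min important - max unimportant; > 0 means strict separation
    n_important: int
    n_unimportant: int
    R_important: np.ndarray = field(repr=False, default=None)
    R_unimportant: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class ClusteringResult:
    spec: EnsembleSpec
    samples: tuple[ClusteringSample, ...]

    @property
    def important_mean(self) -> float:
        return float(np.mean([s.important_mean for s in self.samples]))

    @property
    def gap_fraction(self) -> float:
        """Fraction of samples with strict separation (gap > 0)."""
        return float(np.mean([s.gap > 0 for s in self.samples]))

    def pooled_unimportant(self) -> np.ndarray:
        return np.concatenate([s.R_unimportant for s in self.samples])


def rk_clustering(spec: EnsembleSpec) -> ClusteringResult:
    """Two-cluster experiment: sorted R_k, per-class means and the
    separation gap for ``spec.reps`` connected ER samples with a random
    binary measurement of ``spec.n1`` ones."""
    if spec.measurement != "binary":
        raise ValueError("clustering uses a binary measurement policy")
    rng = np.random.default_rng(spec.seed)
    samples = []
    for _ in range(spec.reps):
        graph = sample_er_graph(spec.n, spec.p, rng)
        M = np.zeros(spec.n)
        M[rng.choice(spec.n, spec.n1, replace=False)] = 1.0
        dec = spectral_decomposition(build_laplacian(graph))
        res = edge_importance(dec, MeasurementVector(M), graph)
        mz = np.array([abs(M[e.target] - M[e.source]) for e in graph.edges])
        imp = res.values[mz == 1.0]
        unimp = res.values[mz == 0.0]
        samples.append(
            ClusteringSample(
                R_sorted=np.sort(res.values)[::-1],
                important_mean=float(imp.mean()) if imp.size else 0.0,
                unimportant_mean=float(unimp.mean()) if unimp.size else 0.0,
                unimportant_max=float(unimp.max()) if unimp.size else 0.0,
                important_min=float(imp.min()) if imp.size else 0.0,
                gap=float(imp.min() - unimp.max()) if imp.size and unimp.size else np.nan,
                n_important=int(imp.size),
                n_unimportant=int(unimp.size),
                R_important=imp,
                R_unimportant=unimp,
            )
        )
    return ClusteringResult(spec=spec, samples=tuple(samples))


@dataclass(frozen=True)
class GradedResult:
    """Graded-measurement experiment: per-edge (|M^T zeta_k|, R_k) pairs and
    the through-origin quadratic fit R_k ~ coef * (M^T zeta_k)^2."""

    spec: EnsembleSpec
    abscissa: np.ndarray  # |M^T zeta_k| pooled over samples
    R: np.ndarray
    coefficient: float
    reference: float  # 1/(n C) with C = 2p


def graded_measurement_experiment(spec: EnsembleSpec) -> GradedResult:
    """Empirical quadratic law for graded measurements: with M uniform on
    [0,1]^n, E[R_k | M] ~ (M^T zeta_k)^2 / (nC); the fitted through-origin
    coefficient is reported against 1/(nC) (not asserted — empirical law)."""
    if spec.measurement != "graded":
        raise ValueError("graded experiment requires the graded policy")
    rng = np.random.default_rng(spec.seed)
    xs, ys = [], []
    for _ in range(spec.reps):
        graph = sample_er_graph(spec.n, spec.p, rng)
        M = rng.random(spec.n)
        dec = spectral_decomposition(build_laplacian(graph))
        res = edge_importance(dec, MeasurementVector(M, mode="graded"), graph)
        mz = np.array([M[e.target] - M[e.source] for e in graph.edges])
        xs.append(np.abs(mz))
        ys.append(res.values)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    x2 = x**2
    coef = float((x2 @ y) / (x2 @ x2))
    return GradedResult(
        spec=spec, abscissa=x, R=y, coefficient=coef,
        reference=1.0 / (spec.n * spec.C),
    )


def connectivity_bound(n: int, p: float) -> float:
    """Upper bound n^2/2 (1-p)^(n-1) on the probability that G(n, p) is
    disconnected (union bound over bipartitions)."""
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    return 0.5 * n**2 * (1.0 - p) ** (n - 1)
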