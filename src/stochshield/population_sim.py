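"""Discrete-time multinomial population process and exact CTMC oracle.

The underlying model is a closed population of ``N_tot`` individuals hopping
on the reaction graph: a continuous-time Markov jump process in which each
individual at node ``i`` moves to ``j`` with per-capita rate ``alpha_ij``.
The discrete-time scheme advances all individuals at a node simultaneously by
a single multinomial draw over destinations (stay probability
``1 - sum_j alpha_ij h``), which preserves counts exactly and can never drive
an occupancy negative — unlike independent binomial draws per edge, which
need resampling.

Population-level stochastic shielding replaces the *fluctuation* of the
transition count on selected edges by zero while keeping its conditional
mean: shielded occupancies evolve with ``N_ij = N_i alpha_ij h + deltaN_ij``
on kept edges (``deltaN_ij`` shared with the full run) and
``N_ij = N_i alpha_ij h`` on neglected edges.  Shielded occupancies become
real-valued once means are substituted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .graph_core import ReactionGraph

__all__ = [
    "PopulationPaths",
    "CTMCTrajectory",
    "rate_matrix",
    "multinomial_step",
    "simulate_population",
    "exact_ctmc",
]


def rate_matrix(graph: ReactionGraph) -> np.ndarray:
    """Per-capita rate matrix ``alpha[i, j]`` (zero diagonal)."""
    n = graph.n_nodes
    alpha = np.zeros((n, n))
    for e in graph.edges:
        alpha[e.source, e.target] += e.rate
    return alpha


def multinomial_step(
    N: np.ndarray, alpha: np.ndarray, h: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Advance integer occupancies one step of length ``h``.

    For every source node ``i`` the destinations of all ``N_i`` individuals
    are drawn from ``Multinomial(N_i, (alpha_i1 h, ..., stay, ..., alpha_iK h))``.
    Returns ``(N_next, counts)`` where ``counts[i, j]`` is the number of
    ``i -> j`` moves this step (diagonal = stayers).  Conditional moments:
    ``E[N_ij | N] = N_i alpha_ij h`` and
    ``Cov[N_ij, N_ij'] = -N_i alpha_ij alpha_ij' h^2`` for ``j != j'``.
    """
    N = np.asarray(N)
    n = alpha.shape[0]
    P = alpha * h
    stay = 1.0 - P.sum(axis=1)
    if np.any(stay < 0):
        raise ValueError("h too large: stay probability negative at some node")
    counts = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        if N[i] == 0:
            continue
        probs = P[i].copy()
        probs[i] = stay[i]
        counts[i] = rng.multinomial(int(N[i]), probs)
    N_next = counts.sum(axis=0)
    return N_next, counts


@dataclass(frozen=True)
class PopulationPaths:
    """Occupancy time series of coupled full and shielded runs.

    ``full`` is integer-valued (n x steps+1); ``shielded`` is real-valued and
    equals ``full`` exactly when no edges are neglected.
    """

    t: np.ndarray
    full: np.ndarray
    shielded: np.ndarray
    neglected: tuple[int, ...]
    n_tot: int
    h: float
    seed: int


def simulate_population(
    graph: ReactionGraph,
    N0: Sequence[int],
    h: float,
    steps: int,
    neglected: Iterable[int] = (),
    seed: int = 0,
) -> PopulationPaths:
    """Run the multinomial population process with and without shielding.

    Both runs share the per-step fluctuations ``deltaN_ij = N_ij - N_i alpha_ij h``
    drawn from the full run's state; the shielded run adds its own conditional
    means, and on the neglected edges the fluctuation is set to zero.  With an
    empty neglected set the runs coincide exactly.
    """
    N0 = np.asarray(N0, dtype=np.int64)
    if np.any(N0 < 0):
        raise ValueError("initial occupancies must be nonnegative")
    alpha = rate_matrix(graph)
    n = graph.n_nodes
    rng = np.random.default_rng(seed)
    negl = sorted(set(int(k) for k in neglected))
    if negl and (negl[0] < 0 or negl[-1] >= graph.n_edges):
        raise IndexError("neglected edge index out of range")
    negl_mask = np.zeros((n, n), dtype=bool)
    for k in negl:
        e = graph.edges[k]
        negl_mask[e.source, e.target] = True

    full = np.empty((n, steps + 1), dtype=np.int64)
    shielded = np.empty((n, steps + 1), dtype=float)
    full[:, 0] = N0
    shielded[:, 0] = N0
    P = alpha * h
    keep = ~negl_mask
    np.fill_diagonal(keep, False)
    for s in range(steps):
        N = full[:, s]
        N_next, counts = multinomial_step(N, alpha, h, rng)
        full[:, s + 1] = N_next
        mean_full = N[:, None] * P
        delta = counts.astype(float) - mean_full  # off-diagonal fluctuations
        Ns = shielded[:, s]
        flux = Ns[:, None] * P + np.where(keep, delta, 0.0)
        shielded[:, s + 1] = Ns + flux.sum(axis=0) - flux.sum(axis=1)
    t = h * np.arange(steps + 1)
    return PopulationPaths(
        t=t, full=full, shielded=shielded, neglected=tuple(negl),
        n_tot=int(N0.sum()), h=h, seed=seed,
    )


@dataclass(frozen=True)
class CTMCTrajectory:
    """Event-driven jump trajectory: piecewise-constant occupancies.

    ``times[j]`` is the time of the j-th jump; ``states[:, j]`` the occupancy
    vector immediately after it (column 0 is the initial state at time 0).
    """

    times: np.ndarray
    states: np.ndarray
    T: float

    def time_average(self, burn_in: float = 0.0) -> np.ndarray:
        """Occupancy mean weighted by holding times after ``burn_in``."""
        return self._moments(burn_in)[0]

    def time_covariance(self, burn_in: float = 0.0) -> np.ndarray:
        """Occupancy covariance weighted by holding times after ``burn_in``."""
        return self._moments(burn_in)[1]

    def _moments(self, burn_in: float) -> tuple[np.ndarray, np.ndarray]:
        edges = np.concatenate([self.times, [self.T]])
        start = np.clip(self.times, burn_in, self.T)
        end = np.clip(edges[1:], burn_in, self.T)
        w = end - start
        total = w.sum()
        if total <= 0:
            raise ValueError("burn_in exceeds the trajectory horizon")
        X = self.states.astype(float)
        mean = (X * w).sum(axis=1) / total
        Xc = X - mean[:, None]
        cov = (Xc * w) @ Xc.T / total
        return mean, cov


def exact_ctmc(
    graph: ReactionGraph,
    N0: Sequence[int],
    T: float,
    seed: int = 0,
    max_events: int = 50_000_000,
) -> CTMCTrajectory:
    """Statistically exact jump-process simulation (direct method).

    Reaction ``k`` fires with propensity ``alpha_k N_{i(k)}``; each firing
    moves one individual along edge ``k``.  Serves as the oracle for the
    multinomial scheme's small-``h`` bias and for the OU correspondence.
    """
    N = np.asarray(N0, dtype=np.int64).copy()
    rng = np.random.default_rng(seed)
    rates = graph.rates()
    src = np.array([e.source for e in graph.edges])
    dst = np.array([e.target for e in graph.edges])
    times = [0.0]
    states = [N.copy()]
    t = 0.0
    for _ in range(max_events):
        prop = rates * N[src]
        total = prop.sum()
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t >= T:
            break
        k = rng.choice(prop.size, p=prop / total)
        N[src[k]] -= 1
        N[dst[k]] += 1
        times.append(t)
        states.append(N.copy())
    else:
        raise RuntimeError("max_events exceeded before reaching horizon T")
    return CTMCTrajectory(
        times=np.array(times), states=np.array(states).T, T=float(T)
    )
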