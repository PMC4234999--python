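"""Hodgkin-Huxley potassium and sodium channel graphs under voltage clamp.

The K+ channel is a 5-state chain (four identical ``n`` subunits; state 5,
all subunits open, conducts).  The Na+ channel is two linked 4-state chains
(three ``m`` activation subunits plus one ``h`` inactivation subunit; state 8,
``m = (1,1,1), h = 1``, conducts): 8 states and 20 reactions.  Rates are
per millisecond with membrane potential ``V`` in mV; the graph Laplacians are
non-symmetric, so the biorthogonal edge-importance formula applies.

At a clamped voltage the channel population is stationary and its
fluctuations are approximated by an OU process whose noise scale per edge is
``sigma_k = sqrt(r_k(V) Nbar_{i(k)}(V))`` — the square root of the stationary
propensity, as in the chemical Langevin construction — with
``Nbar = pi(V) N_tot``.  Edge importance is reported for ``N_tot = 1``
(per-channel, "nominal units"); any population size scales every R_k by the
same factor and leaves rankings and crossovers unchanged.

Edge numbering pairs each reversible transition as (2p-1, 2p) with the
forward (upward) direction first:

* K+ (8 edges):  1:1->2(4a)  2:2->1(b)   3:2->3(3a)  4:3->2(2b)
                 5:3->4(2a)  6:4->3(3b)  7:4->5(a)   8:5->4(4b)
  with a = alpha_n(V), b = beta_n(V).
* Na+ (20 edges): m-transitions of the h=0 chain (states 1-4), then of the
  h=1 chain (states 5-8), then the h-transitions:
                 1:1->2(3am)   2:2->1(bm)   3:2->3(2am)   4:3->2(2bm)
                 5:3->4(am)    6:4->3(3bm)  7:5->6(3am)   8:6->5(bm)
                 9:6->7(2am)  10:7->6(2bm) 11:7->8(am)   12:8->7(3bm)
                13:1->5(ah)   14:5->1(bh)  15:2->6(ah)   16:6->2(bh)
                17:3->7(ah)   18:7->3(bh)  19:4->8(ah)   20:8->4(bh)
  so edges 11/12 join state 7 to the conducting state 8 (activation) and
  19/20 join state 4 to state 8 (inactivation), the two pairs whose relative
  importance swaps with voltage.

(Indices above are 1-based as in the printed figures; the code is 0-based.)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Callable, Sequence

import numpy as np

from .edge_importance import edge_importance
from .graph_core import (
    Edge,
    MeasurementVector,
    ReactionGraph,
    build_laplacian,
    spectral_decomposition,
    stationary_distribution,
)

__all__ = [
    "ChannelSpec",
    "VoltageSweepResult",
    "k_channel_rates",
    "na_channel_rates",
    "potassium_channel",
    "sodium_channel",
    "build_channel_graph",
    "channel_importance",
    "voltage_sweep",
    "find_crossover",
]


def _phi(x: np.ndarray | float) -> np.ndarray | float:
    """Numerically stable x / (1 - exp(-x)).

    The removable singularity at x = 0 is bridged by a 4th-order Taylor
    branch for |x| < 1e-4, keeping machine-precision continuity without
    special-casing exact grid hits.
    """
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-4
    safe = np.where(small, 1.0, x)
    out = np.where(
        small,
        1.0 + x / 2.0 + x**2 / 12.0 - x**4 / 720.0,
        safe / (1.0 - np.exp(-safe)),
    )
    return out if out.ndim else float(out)


def k_channel_rates(V: float) -> tuple[float, float]:
    """Potassium subunit rates (alpha_n, beta_n) in 1/ms at voltage V in mV."""
    alpha_n = 0.1 * _phi(0.1 * (V + 55.0))
    beta_n = 0.125 * np.exp(-(V + 65.0) / 80.0)
    return float(alpha_n), float(beta_n)


def na_channel_rates(V: float) -> tuple[float, float, float, float]:
    """Sodium subunit rates (alpha_m, beta_m, alpha_h, beta_h) in 1/ms."""
    alpha_m = _phi((V + 40.0) / 10.0)
    beta_m = 4.0 * np.exp(-(V + 65.0) / 18.0)
    alpha_h = 0.07 * np.exp(-(V + 65.0) / 20.0)
    beta_h = 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))
    return float(alpha_m), float(beta_m), float(alpha_h), float(beta_h)


@dataclass(frozen=True)
class ChannelSpec:
    """Voltage-dependent channel definition.

    ``edge_template(V)`` returns the ordered (source, target, rate) list;
    ``conducting`` is the 0-based conducting state; ``v_rev`` the reversal
    potential in mV; ``n_tot`` the channel count setting the noise scale.
    """

    name: str
    n_states: int
    conducting: int
    v_rev: float
    edge_template: Callable[[float], list[tuple[int, int, float]]]
    n_tot: float = 1.0

    @property
    def measurement(self) -> MeasurementVector:
        M = np.zeros(self.n_states)
        M[self.conducting] = 1.0
        return MeasurementVector(M)

    @property
    def n_edges(self) -> int:
        return len(self.edge_template(-65.0))


def _k_edges(V: float) -> list[tuple[int, int, float]]:
    a, b = k_channel_rates(V)
    return [
        (0, 1, 4 * a), (1, 0, b),
        (1, 2, 3 * a), (2, 1, 2 * b),
        (2, 3, 2 * a), (3, 2, 3 * b),
        (3, 4, a), (4, 3, 4 * b),
    ]


def _na_edges(V: float) -> list[tuple[int, int, float]]:
    am, bm, ah, bh = na_channel_rates(V)
    m_chain = lambda o: [
        (o + 0, o + 1, 3 * am), (o + 1, o + 0, bm),
        (o + 1, o + 2, 2 * am), (o + 2, o + 1, 2 * bm),
        (o + 2, o + 3, am), (o + 3, o + 2, 3 * bm),
    ]
    h_links = [link for s in range(4) for link in ((s, s + 4, ah), (s + 4, s, bh))]
    return m_chain(0) + m_chain(4) + h_links


def potassium_channel(n_tot: float = 1.0) -> ChannelSpec:
    """Classic HH K+ channel: 5-state chain, state 5 conducting, V_rev = -77 mV."""
    return ChannelSpec("K", 5, 4, -77.0, _k_edges, n_tot)


def sodium_channel(n_tot: float = 1.0) -> ChannelSpec:
    """Classic HH Na+ channel: 8 states, state 8 conducting, V_rev = +45 mV."""
    return ChannelSpec("Na", 8, 7, 45.0, _na_edges, n_tot)


def build_channel_graph(spec: ChannelSpec, V: float) -> tuple[ReactionGraph, np.ndarray]:
    """Reaction graph at voltage ``V`` with stationary noise scales.

    Returns ``(graph, pi)`` where ``pi`` is the stationary distribution and
    each edge carries ``sigma_k = sqrt(r_k pi_{i(k)} n_tot)``.
    """
    template = spec.edge_template(V)
    bare = ReactionGraph(
        spec.n_states, tuple(Edge(i, j, r, 1.0) for i, j, r in template)
    )
    pi = stationary_distribution(spectral_decomposition(build_laplacian(bare)))
    sigmas = [np.sqrt(r * pi[i] * spec.n_tot) for i, j, r in template]
    return bare.with_sigmas(sigmas), pi


def channel_importance(spec: ChannelSpec, V: float):
    """Edge importance of every reaction at one voltage (non-symmetric
    formula); also returns the stationary distribution."""
    graph, pi = build_channel_graph(spec, V)
    dec = spectral_decomposition(build_laplacian(graph))
    return edge_importance(dec, spec.measurement, graph), pi


def _pair_index(k: int) -> int:
    """Reversible-pair id (0-based) of edge k under the (2p-1, 2p) pairing."""
    return k // 2


@dataclass(frozen=True)
class VoltageSweepResult:
    """Per-edge importance, occupancy and current-variance voltage sweeps."""

    spec: ChannelSpec
    voltages: np.ndarray
    R: np.ndarray = field(repr=False)  # m x len(voltages)
    pi: np.ndarray = field(repr=False)  # n x len(voltages)
    current_variance: np.ndarray = field(repr=False)  # R * (V - v_rev)^2
    maximal_pair: np.ndarray = None  # 0-based pair id per voltage

    def maximal_pair_edges(self, vi: int) -> tuple[int, int]:
        """1-based edge labels of the maximal pair at voltage index ``vi``."""
        p = int(self.maximal_pair[vi])
        return (2 * p + 1, 2 * p + 2)


def voltage_sweep(spec: ChannelSpec, voltages: Sequence[float]) -> VoltageSweepResult:
    """Compute R_k(V), pi(V) and the nominal current variance
    R_k(V) (V - V_rev)^2 on a voltage grid, tracking the maximal reversible
    pair at each point."""
    voltages = np.asarray(voltages, dtype=float)
    m = spec.n_edges
    R = np.empty((m, voltages.size))
    pi = np.empty((spec.n_states, voltages.size))
    for vi, V in enumerate(voltages):
        res, p = channel_importance(spec, float(V))
        R[:, vi] = res.values
        pi[:, vi] = p
    cur = R * (voltages[np.newaxis, :] - spec.v_rev) ** 2
    # maximal pair by the mean of each reversible pair (the two directions
    # agree to rounding under detailed balance)
    pair_R = R.reshape(m // 2, 2, -1).mean(axis=1)
    maximal = pair_R.argmax(axis=0)
    return VoltageSweepResult(
        spec=spec, voltages=voltages, R=R, pi=pi,
        current_variance=cur, maximal_pair=maximal,
    )


def find_crossover(sweep: VoltageSweepResult, refine_tol: float = 0.1) -> list[float]:
    """Voltages where the identity of the maximal reversible pair changes.

    Each sign change of the difference between the two competing pairs'
    importance curves is refined by bisection to ``refine_tol`` mV.  Returns
    an empty list when one pair dominates throughout (the K+ channel).
    Requires grid spacing <= 1 mV for reliable detection.
    """
    v = sweep.voltages
    if v.size > 1 and np.max(np.diff(v)) > 1.0 + 1e-9:
        raise ValueError("crossover detection requires grid spacing <= 1 mV")
    spec = sweep.spec
    crossings: list[float] = []
    mp = sweep.maximal_pair
    for idx in np.flatnonzero(np.diff(mp) != 0):
        pa, pb = int(mp[idx]), int(mp[idx + 1])

        def diff(V: float) -> float:
            res, _ = channel_importance(spec, V)
            pair_R = res.values.reshape(-1, 2).mean(axis=1)
            return float(pair_R[pa] - pair_R[pb])

        lo, hi = float(v[idx]), float(v[idx + 1])
        flo = diff(lo)
        if flo == 0.0:
            crossings.append(lo)
            continue
        while hi - lo > refine_tol:
            mid = (lo + hi) / 2
            if diff(mid) * flo > 0:
                lo = mid
            else:
                hi = mid
        crossings.append((lo + hi) / 2)
    return crossings


def k_stationary_binomial(V: float) -> np.ndarray:
    """Closed-form K+ occupancy: four independent identical subunits, each
    open with probability alpha_n/(alpha_n+beta_n) — a binomial oracle for
    the generic stationary distribution."""
    a, b = k_channel_rates(V)
    q = a / (a + b)
    return np.array([comb(4, k) * q**k * (1 - q) ** (4 - k) for k in range(5)])
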