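"""Plain-text readers/writers and built-in fixtures.

Edge lists are TSV with header ``source  target  rate  sigma`` (1-based node
indices, ``sigma`` optional, default 1.0).  Measurement vectors are
one-value-per-line text.  Dense matrices round-trip through CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .graph_core import Edge, MeasurementVector, ReactionGraph
from .hh_channels import build_channel_graph, potassium_channel, sodium_channel

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "read_measurement",
    "write_measurement",
    "read_matrix",
    "write_matrix",
    "load_fixture",
    "FIXTURES",
]


class EdgeListError(ValueError):
    """Malformed edge-list file; the message carries the offending line."""


def read_edge_list(path: str | Path) -> ReactionGraph:
    """Read a TSV edge list (1-based indices) into a :class:`ReactionGraph`."""
    path = Path(path)
    edges: list[Edge] = []
    n_nodes = 0
    with path.open() as fh:
        header = fh.readline().strip().split("\t")
        expected = ["source", "target", "rate"]
        if [h.strip().lower() for h in header[:3]] != expected:
            raise EdgeListError(
                f"{path}:1: header must start with 'source\\ttarget\\trate'"
            )
        has_sigma = len(header) >= 4 and header[3].strip().lower() == "sigma"
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                s, t = int(parts[0]), int(parts[1])
                rate = float(parts[2])
                sigma = float(parts[3]) if has_sigma and len(parts) > 3 else 1.0
            except (ValueError, IndexError) as exc:
                raise EdgeListError(f"{path}:{lineno}: {exc}") from None
            if s < 1 or t < 1:
                raise EdgeListError(f"{path}:{lineno}: node indices are 1-based")
            if s == t:
                raise EdgeListError(f"{path}:{lineno}: self-loop {s}->{t}")
            if rate <= 0:
                raise EdgeListError(f"{path}:{lineno}: rate must be > 0")
            if sigma < 0:
                raise EdgeListError(f"{path}:{lineno}: sigma must be >= 0")
            edges.append(Edge(s - 1, t - 1, rate, sigma))
            n_nodes = max(n_nodes, s, t)
    return ReactionGraph(n_nodes, tuple(edges))


def write_edge_list(graph: ReactionGraph, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("source\ttarget\trate\tsigma\n")
        for e in graph.edges:
            fh.write(
                f"{e.source + 1}\t{e.target + 1}\t"
                f"{float(e.rate)!r}\t{float(e.sigma)!r}\n"
            )


def read_measurement(path: str | Path) -> MeasurementVector:
    values = [float(line) for line in Path(path).read_text().split()]
    return MeasurementVector.from_values(values)


def write_measurement(M: MeasurementVector, path: str | Path) -> None:
    Path(path).write_text("".join(f"{float(v)!r}\n" for v in M.values))


def read_matrix(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", ndmin=2)


def write_matrix(A: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(A), delimiter=",", fmt="%.17g")


def _threestate() -> tuple[ReactionGraph, MeasurementVector]:
    """3-state chain with unit rates and unit noise scales; only state 3 is
    observed (the conducting state of the toy ion-channel example)."""
    edges = (Edge(0, 1, 1.0), Edge(1, 0, 1.0), Edge(1, 2, 1.0), Edge(2, 1, 1.0))
    return ReactionGraph(3, edges), MeasurementVector(np.array([0.0, 0.0, 1.0]))


def _hh_fixture(kind: str, V: float = -65.0):
    spec = potassium_channel() if kind == "K" else sodium_channel()
    graph, _ = build_channel_graph(spec, V)
    return graph, spec.measurement


FIXTURES = ("threestate", "hhk", "hhna")


def load_fixture(name: str, V: float = -65.0) -> tuple[ReactionGraph, MeasurementVector]:
    """Built-in graph/measurement pairs: ``threestate``, ``hhk``, ``hhna``
    (HH channels evaluated at voltage ``V``, default -65 mV)."""
    if name == "threestate":
        return _threestate()
    if name == "hhk":
        return _hh_fixture("K", V)
    if name == "hhna":
        return _hh_fixture("Na", V)
    raise KeyError(f"unknown fixture {name!r}; available: {FIXTURES}")
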