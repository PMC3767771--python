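"""Typed bipartite regulation graphs.

Thresholding the z-score matrix at a stringency ``t_B`` yields an unweighted
bipartite graph between regulators and targets.  Edges keep only the sign of
the underlying score: ``UP`` for ``z >= t_B`` and ``DOWN`` for ``z <= -t_B``
(inclusive comparisons).  A (regulator, target) pair has a single z-score and
therefore carries at most one edge.
"""

from __future__ import annotations

import enum
import warnings
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .zscores import ZScoreMatrix

SIDE_REGULATOR = "regulator"
SIDE_TARGET = "target"
SIDES = (SIDE_REGULATOR, SIDE_TARGET)


class EdgeType(enum.Enum):
    """Sign of a regulation edge: up- or down-regulation."""

    UP = "up"
    DOWN = "down"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class RegulationGraph:
    """Bipartite graph with UP/DOWN typed edges.

    Parameters
    ----------
    regulators, targets:
        Node labels for the two sides.  Labels must be unique and the two
        sides disjoint.
    edges:
        Mapping ``(regulator, target) -> EdgeType``.  At most one edge per
        pair by construction.
    threshold:
        Record of the ``t_B`` used to build the graph (or ``"synthetic"``).
    """

    def __init__(self, regulators: Iterable[str], targets: Iterable[str],
                 edges: Mapping[tuple[str, str], EdgeType] | None = None,
                 threshold=None):
        self.regulators = [str(r) for r in regulators]
        self.targets = [str(t) for t in targets]
        reg_set, tgt_set = set(self.regulators), set(self.targets)
        if len(reg_set) != len(self.regulators):
            raise ValueError("duplicate regulator labels")
        if len(tgt_set) != len(self.targets):
            raise ValueError("duplicate target labels")
        overlap = reg_set & tgt_set
        if overlap:
            raise ValueError(f"labels on both sides: {sorted(overlap)[:3]}")
        self.edges: dict[tuple[str, str], EdgeType] = {}
        for (r, t), etype in (edges or {}).items():
            if r not in reg_set or t not in tgt_set:
                raise ValueError(f"edge ({r!r}, {t!r}) does not respect the bipartition")
            self.edges[(r, t)] = EdgeType(etype)
        self.threshold = threshold

    # -- basic queries ----------------------------------------------------
    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edges_of_type(self, etype: EdgeType) -> list[tuple[str, str]]:
        return [pair for pair, e in self.edges.items() if e is etype]

    def has_edge(self, regulator: str, target: str) -> bool:
        return (regulator, target) in self.edges

    def degree_signature(self, side: str) -> dict[str, tuple[int, int]]:
        """Per-node ``(up_degree, down_degree)`` on the requested side."""
        if side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {side!r}")
        nodes = self.regulators if side == SIDE_REGULATOR else self.targets
        sig = {n: [0, 0] for n in nodes}
        for (r, t), etype in self.edges.items():
            node = r if side == SIDE_REGULATOR else t
            sig[node][0 if etype is EdgeType.UP else 1] += 1
        return {n: (u, d) for n, (u, d) in sig.items()}

    def canonical_edges(self) -> frozenset[tuple[str, str, str]]:
        """Hashable canonical form, useful for graph-identity checks."""
        return frozenset((r, t, e.value) for (r, t), e in self.edges.items())

    def copy(self) -> "RegulationGraph":
        return RegulationGraph(self.regulators, self.targets, dict(self.edges),
                               self.threshold)

    # -- array views ------------------------------------------------------
    def biadjacency(self) -> tuple[np.ndarray, np.ndarray]:
        """Boolean regulator x target matrices ``(M_up, M_down)``.

        Rows follow ``self.regulators`` order, columns ``self.targets``.
        """
        ri = {r: i for i, r in enumerate(self.regulators)}
        ti = {t: j for j, t in enumerate(self.targets)}
        m_up = np.zeros((len(self.regulators), len(self.targets)), dtype=bool)
        m_down = np.zeros_like(m_up)
        for (r, t), etype in self.edges.items():
            (m_up if etype is EdgeType.UP else m_down)[ri[r], ti[t]] = True
        return m_up, m_down

    # -- conversions ------------------------------------------------------
    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.graph["threshold"] = "" if self.threshold is None else str(self.threshold)
        for r in self.regulators:
            g.add_node(r, side=SIDE_REGULATOR)
        for t in self.targets:
            g.add_node(t, side=SIDE_TARGET)
        for (r, t), etype in self.edges.items():
            g.add_edge(r, t, type=etype.value)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "RegulationGraph":
        regulators = [n for n, d in g.nodes(data=True) if d.get("side") == SIDE_REGULATOR]
        targets = [n for n, d in g.nodes(data=True) if d.get("side") == SIDE_TARGET]
        reg_set = set(regulators)
        edges = {}
        for u, v, d in g.edges(data=True):
            r, t = (u, v) if u in reg_set else (v, u)
            edges[(r, t)] = EdgeType(d["type"])
        threshold = g.graph.get("threshold") or None
        return cls(regulators, targets, edges, threshold)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RegulationGraph):
            return NotImplemented
        return (set(self.regulators) == set(other.regulators)
                and set(self.targets) == set(other.targets)
                and self.edges == other.edges)


def build_regulation_graph(Z: ZScoreMatrix, t_B: float) -> RegulationGraph:
    """Threshold a z-score matrix into a typed bipartite regulation graph.

    An edge ``(r, t, UP)`` is created iff ``z(r, t) >= t_B`` and
    ``(r, t, DOWN)`` iff ``z(r, t) <= -t_B``; comparisons are inclusive
    ("at least as large as" in absolute value).  Missing entries yield no
    edge.  At ``t_B = 0`` every non-missing entry produces an edge and an
    exact zero is classified UP by the ``>=`` rule; a warning is emitted
    because that boundary case is rarely what one wants.
    """
    t_B = float(t_B)
    if t_B < 0:
        raise ValueError(f"t_B must be non-negative, got {t_B}")
    if t_B == 0:
        warnings.warn("t_B = 0 turns every measured entry into an edge; "
                      "z = 0 is classified as up-regulation by the inclusive rule",
                      stacklevel=2)
    edges: dict[tuple[str, str], EdgeType] = {}
    vals = Z.values
    for i, r in enumerate(Z.regulator_ids):
        for j, t in enumerate(Z.target_ids):
            z = vals[i, j]
            if np.isnan(z):
                continue
            if z >= t_B:
                edges[(r, t)] = EdgeType.UP
            elif z <= -t_B:
                edges[(r, t)] = EdgeType.DOWN
    return RegulationGraph(Z.regulator_ids, Z.target_ids, edges, threshold=t_B)


# ---------------------------------------------------------------------------
# File formats: GraphML keeps the full node sets (including isolated nodes);
# the 3-column edge list is a convenience view and only carries incident nodes.

def write_graphml(G: RegulationGraph, path) -> None:
    nx.write_graphml(G.to_networkx(), path)


def read_graphml(path) -> RegulationGraph:
    return RegulationGraph.from_networkx(nx.read_graphml(path))


def write_edge_list(G: RegulationGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("regulator\ttarget\ttype\n")
        for (r, t), etype in sorted(G.edges.items()):
            fh.write(f"{r}\t{t}\t{etype.value}\n")


def read_edge_list(path) -> RegulationGraph:
    edges: dict[tuple[str, str], EdgeType] = {}
    regulators: list[str] = []
    targets: list[str] = []
    seen_r: set[str] = set()
    seen_t: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["regulator", "target", "type"]:
            raise ValueError(f"unexpected edge-list header: {header}")
        for line in fh:
            if not line.strip():
                continue
            r, t, etype = line.rstrip("\n").split("\t")[:3]
            if r not in seen_r:
                seen_r.add(r)
                regulators.append(r)
            if t not in seen_t:
                seen_t.add(t)
                targets.append(t)
            edges[(r, t)] = EdgeType(etype)
    return RegulationGraph(regulators, targets, edges)


def read_graph(path) -> RegulationGraph:
    """Load a regulation graph from GraphML or an edge-list TSV by extension."""
    p = str(path)
    if p.endswith(".graphml"):
        return read_graphml(p)
    return read_edge_list(p)
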