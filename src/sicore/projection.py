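"""Significance-filtered one-mode projection of regulation graphs.

Two same-side nodes *co-occur* when they share a neighbour on the opposite
side.  Three patterns are distinguished:

* ``CO_UP``: both nodes are linked to a common neighbour by UP edges
  (symmetric, unordered pairs);
* ``CO_DOWN``: likewise with DOWN edges;
* ``ANTAGONISTIC``: the source node is linked by DOWN and the head node by UP
  to the same neighbour (directional; the arrow points from the
  down-regulated / down-regulating member to the up-regulated /
  up-regulating one).

For every pair and pattern with at least one observed co-occurrence, an
empirical p-value is estimated as the fraction of degree-preserving null
samples whose count matches or exceeds the observed count.  Pairs that never
co-occur have an empirical p-value of 1 by definition (a count of 0 is
reached in every sample).
"""

from __future__ import annotations

import enum
import json
import math
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .graph import SIDE_REGULATOR, SIDE_TARGET, SIDES, RegulationGraph
from .nullmodel import SwapChainConfig, _ChainState


class Pattern(enum.Enum):
    CO_UP = "co_up"
    CO_DOWN = "co_down"
    ANTAGONISTIC = "antagonistic"

    @property
    def symmetric(self) -> bool:
        return self is not Pattern.ANTAGONISTIC

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _pattern_count_matrices(m_up: np.ndarray, m_down: np.ndarray,
                            side: str) -> dict[Pattern, np.ndarray]:
    """Co-occurrence count matrices for all three patterns.

    For the target side, entry ``(i, j)`` of the antagonistic matrix counts
    regulators that DOWN-regulate target ``i`` and UP-regulate target ``j``
    (edge direction ``i -> j``); for the regulator side, regulators ``i``
    down-regulating and ``j`` up-regulating a common target.
    """
    if side == SIDE_TARGET:
        co_up = m_up.T @ m_up
        co_down = m_down.T @ m_down
        ant = m_down.T @ m_up
    else:
        co_up = m_up @ m_up.T
        co_down = m_down @ m_down.T
        ant = m_down @ m_up.T
    return {
        Pattern.CO_UP: co_up.astype(np.int64),
        Pattern.CO_DOWN: co_down.astype(np.int64),
        Pattern.ANTAGONISTIC: ant.astype(np.int64),
    }


class PairStatTable:
    """Per-pair, per-pattern co-occurrence counts and empirical p-values.

    Counts are held as dense square matrices over ``nodes`` (diagonal
    ignored).  ``exceed`` counts null samples whose pair count matched or
    exceeded the observed count; it is ``None`` for a counts-only table.
    """

    def __init__(self, side: str, nodes: list[str],
                 observed: dict[Pattern, np.ndarray],
                 exceed: dict[Pattern, np.ndarray] | None = None,
                 n_samples: int | None = None,
                 meta: dict | None = None):
        if side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {side!r}")
        self.side = side
        self.nodes = [str(n) for n in nodes]
        n = len(self.nodes)
        self.observed = {Pattern(p): np.array(m, dtype=np.int64) for p, m in observed.items()}
        for m in self.observed.values():
            if m.shape != (n, n):
                raise ValueError("count matrix shape does not match node count")
            np.fill_diagonal(m, 0)  # self-pairs are meaningless
        self.exceed = None
        if exceed is not None:
            if n_samples is None:
                raise ValueError("n_samples required alongside exceed counts")
            self.exceed = {Pattern(p): np.array(m, dtype=np.int64) for p, m in exceed.items()}
            for p, m in self.exceed.items():
                if m.shape != (n, n):
                    raise ValueError("exceed matrix shape does not match node count")
                if (m > n_samples).any():
                    raise ValueError("exceed count larger than n_samples")
                np.fill_diagonal(m, n_samples)  # zero observed => p = 1
        self.n_samples = n_samples
        self.meta = dict(meta or {})

    @property
    def has_pvalues(self) -> bool:
        return self.exceed is not None

    def observed_matrix(self, pattern: Pattern) -> np.ndarray:
        return self.observed[Pattern(pattern)]

    def p_emp_matrix(self, pattern: Pattern) -> np.ndarray:
        """Empirical p-values ``exceed / n_samples``; 1 wherever observed = 0."""
        if self.exceed is None:
            raise ValueError("this table holds counts only; run empirical_pvalues")
        return self.exceed[Pattern(pattern)] / self.n_samples

    # -- pair-wise views --------------------------------------------------
    def _pair_indices(self, pattern: Pattern) -> tuple[np.ndarray, np.ndarray]:
        n = len(self.nodes)
        if Pattern(pattern).symmetric:
            return np.triu_indices(n, k=1)
        off = ~np.eye(n, dtype=bool)
        return np.where(off)

    def candidate_arrays(self, pattern: Pattern):
        """All candidate pairs of a pattern with their statistics.

        Returns ``(pairs, observed, p_emp)`` where ``pairs`` is a list of
        id tuples — unordered ``(a, b)`` with ``a`` first in node order for
        symmetric patterns, ordered ``(source, head)`` for the antagonistic
        one — covering the full candidate universe including zero-count
        pairs.
        """
        pattern = Pattern(pattern)
        ii, jj = self._pair_indices(pattern)
        pairs = [(self.nodes[i], self.nodes[j]) for i, j in zip(ii.tolist(), jj.tolist())]
        obs = self.observed[pattern][ii, jj]
        p = self.p_emp_matrix(pattern)[ii, jj] if self.exceed is not None else None
        return pairs, obs, p

    def pairs_frame(self, min_observed: int = 1) -> pd.DataFrame:
        """Long-format table of pairs with ``observed >= min_observed``."""
        rows = []
        for pattern in Pattern:
            ii, jj = self._pair_indices(pattern)
            obs = self.observed[pattern][ii, jj]
            keep = obs >= min_observed
            for i, j, o in zip(ii[keep].tolist(), jj[keep].tolist(), obs[keep].tolist()):
                row = {
                    "pattern": pattern.value,
                    "node_a": self.nodes[i],
                    "node_b": self.nodes[j],
                    "observed": o,
                }
                if self.exceed is not None:
                    row["exceed"] = int(self.exceed[pattern][i, j])
                    row["n_samples"] = self.n_samples
                    row["p_emp"] = row["exceed"] / self.n_samples
                rows.append(row)
        return pd.DataFrame(rows)

    # -- persistence ------------------------------------------------------
    def to_tsv(self, prefix) -> tuple[Path, Path]:
        """Write ``<prefix>.pairs.tsv`` plus a JSON sidecar with the node universe."""
        prefix = Path(prefix)
        pairs_path = prefix.with_suffix(prefix.suffix + ".pairs.tsv")
        meta_path = prefix.with_suffix(prefix.suffix + ".pairs.meta.json")
        self.pairs_frame().to_csv(pairs_path, sep="\t", index=False)
        meta = {
            "side": self.side,
            "nodes": self.nodes,
            "n_samples": self.n_samples,
            "has_pvalues": self.has_pvalues,
            **self.meta,
        }
        meta_path.write_text(json.dumps(meta, indent=2))
        return pairs_path, meta_path

    @classmethod
    def from_tsv(cls, prefix) -> "PairStatTable":
        prefix = Path(prefix)
        pairs_path = prefix.with_suffix(prefix.suffix + ".pairs.tsv")
        meta_path = prefix.with_suffix(prefix.suffix + ".pairs.meta.json")
        meta = json.loads(meta_path.read_text())
        nodes = meta["nodes"]
        n = len(nodes)
        idx = {x: i for i, x in enumerate(nodes)}
        n_samples = meta["n_samples"]
        observed = {p: np.zeros((n, n), dtype=np.int64) for p in Pattern}
        exceed = None
        if meta["has_pvalues"]:
            # unlisted pairs have observed 0, hence every sample ties or exceeds
            exceed = {p: np.full((n, n), n_samples, dtype=np.int64) for p in Pattern}
        df = pd.read_csv(pairs_path, sep="\t")
        for row in df.itertuples(index=False):
            pattern = Pattern(row.pattern)
            i, j = idx[row.node_a], idx[row.node_b]
            observed[pattern][i, j] = row.observed
            if pattern.symmetric:
                observed[pattern][j, i] = row.observed
            if exceed is not None:
                exceed[pattern][i, j] = row.exceed
                if pattern.symmetric:
                    exceed[pattern][j, i] = row.exceed
        extra = {k: v for k, v in meta.items()
                 if k not in ("side", "nodes", "n_samples", "has_pvalues")}
        return cls(meta["side"], nodes, observed, exceed, n_samples, meta=extra)


def count_cooccurrences(G: RegulationGraph, side: str) -> PairStatTable:
    """Observed co-occurrence counts per pair and pattern (no p-values)."""
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}, got {side!r}")
    m_up, m_down = (m.astype(np.float32) for m in G.biadjacency())
    observed = _pattern_count_matrices(m_up, m_down, side)
    nodes = G.targets if side == SIDE_TARGET else G.regulators
    return PairStatTable(side, nodes, observed)


def empirical_pvalues(G: RegulationGraph, side: str,
                      cfg: SwapChainConfig) -> PairStatTable:
    """Estimate empirical p-values against the degree-preserving null.

    For every pair and pattern, ``p_emp = (#null samples with count >=
    observed) / n_samples``.  Zero-count pairs come out at exactly 1 (every
    sample ties the observation).  Reproducible for a fixed ``cfg.seed``.
    """
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}, got {side!r}")
    if cfg.n_samples < 1:
        raise ValueError("cfg.n_samples must be >= 1")
    state = _ChainState(G)
    observed = _pattern_count_matrices(*state.matrices(), side)
    exceed = {p: np.zeros_like(observed[p]) for p in Pattern}
    rng = np.random.default_rng(cfg.seed)
    gap = cfg.resolved_gap(G)
    for _ in range(cfg.n_samples):
        state.run(rng, gap)
        counts = _pattern_count_matrices(*state.matrices(), side)
        for p in Pattern:
            exceed[p] += counts[p] >= observed[p]
    nodes = G.targets if side == SIDE_TARGET else G.regulators
    meta = {
        "seed": cfg.seed,
        "swaps_per_sample": gap,
        "attempted_swaps": state.attempted,
        "accepted_swaps": state.accepted,
        "acceptance_rate": state.accepted / state.attempted if state.attempted else 0.0,
    }
    return PairStatTable(side, nodes, observed, exceed, cfg.n_samples, meta=meta)


class CoRegulationGraph:
    """One-mode projection retaining only significant co-occurrences.

    ``edges[pattern]`` maps a pair (unordered for the symmetric patterns,
    ordered ``(source, head)`` for the antagonistic one) to
    ``(observed_count, p_emp)``.
    """

    def __init__(self, side: str, nodes: list[str], tau_P: float,
                 edges: dict[Pattern, dict[tuple[str, str], tuple[int, float]]]):
        self.side = side
        self.nodes = list(nodes)
        self.tau_P = float(tau_P)
        self.edges = {Pattern(p): dict(d) for p, d in edges.items()}
        for p in Pattern:
            self.edges.setdefault(p, {})

    def n_edges(self, pattern: Pattern | None = None) -> int:
        if pattern is not None:
            return len(self.edges[Pattern(pattern)])
        return sum(len(d) for d in self.edges.values())

    def pattern_pairs(self, pattern: Pattern) -> set[tuple[str, str]]:
        return set(self.edges[Pattern(pattern)])

    def pattern_subgraph(self, pattern: Pattern) -> nx.Graph:
        """Undirected view of one pattern (antagonistic direction ignored).

        Contains only nodes incident to at least one retained edge.
        """
        g = nx.Graph()
        for (a, b), (obs, p) in self.edges[Pattern(pattern)].items():
            g.add_edge(a, b, observed=obs, p_emp=p)
        return g

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph(side=self.side, tau_P=self.tau_P)
        g.add_nodes_from(self.nodes)
        for pattern, edges in self.edges.items():
            for (a, b), (obs, p) in edges.items():
                g.add_edge(a, b, pattern=pattern.value, observed=obs, p_emp=p,
                           directed=not pattern.symmetric)
                if pattern.symmetric:
                    # stored once per unordered pair; direction carries no meaning
                    pass
        return g

    def edges_frame(self) -> pd.DataFrame:
        rows = [
            {"pattern": pattern.value, "node_a": a, "node_b": b,
             "observed": obs, "p_emp": p}
            for pattern, edges in self.edges.items()
            for (a, b), (obs, p) in sorted(edges.items())
        ]
        return pd.DataFrame(rows)


def build_coregulation_graph(stats: PairStatTable, tau_P: float) -> CoRegulationGraph:
    """Retain exactly the pairs with ``observed >= 1`` and ``p_emp <= tau_P``.

    The retention rule is inclusive; antagonistic directionality is
    preserved.
    """
    if not 0.0 <= tau_P <= 1.0:
        raise ValueError(f"tau_P must be in [0, 1], got {tau_P}")
    if not stats.has_pvalues:
        raise ValueError("stats table has no p-values; run empirical_pvalues first")
    edges: dict[Pattern, dict[tuple[str, str], tuple[int, float]]] = {}
    for pattern in Pattern:
        pairs, obs, p = stats.candidate_arrays(pattern)
        keep = (obs >= 1) & (p <= tau_P)
        edges[pattern] = {
            pairs[k]: (int(obs[k]), float(p[k]))
            for k in np.flatnonzero(keep)
        }
    return CoRegulationGraph(stats.side, stats.nodes, tau_P, edges)


def connected_groups(C: CoRegulationGraph, pattern: Pattern,
                     min_size: int = 2) -> list[list[str]]:
    """Connected components of one pattern's subgraph, direction ignored.

    Only components with at least ``min_size`` nodes are returned, ordered by
    descending size and then lexicographically by their sorted member lists.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    g = C.pattern_subgraph(pattern)
    groups = [sorted(comp) for comp in nx.connected_components(g)
              if len(comp) >= min_size]
    groups.sort(key=lambda grp: (-len(grp), grp))
    return groups
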