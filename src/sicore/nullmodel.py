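"""Degree-preserving null model for typed bipartite graphs.

The null hypothesis behind the significance assessment is: "the observed
co-occurrence is explained by the per-node numbers of up- and down-regulations
alone".  Null graphs are sampled uniformly from the set of all simple
bipartite graphs that share the observed graph's per-type degree signature,
by running a Markov chain of *same-type edge swaps*:

* pick an edge type with probability proportional to that type's edge count;
* pick two distinct edges ``(a, b)`` and ``(c, d)`` of that type uniformly;
* if neither slot ``(a, d)`` nor ``(c, b)`` carries an edge of *either* type,
  replace the two edges by ``(a, d)`` and ``(c, b)`` (same type), otherwise
  leave the graph unchanged.

Rejected proposals count as chain steps (lazy MCMC self-loops), which keeps
the uniform distribution stationary under the symmetric proposal.  A
(regulator, target) pair has a single underlying z-score, hence the conflict
rule spans both edge types.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .graph import EdgeType, RegulationGraph

_UP, _DOWN = 1, 2


@dataclass(frozen=True)
class SwapChainConfig:
    """Sampling parameters for the edge-swap chain.

    ``swaps_per_sample=None`` resolves to ``10 * |E|`` attempted swaps
    between consecutive samples; burn-in equals one inter-sample gap (the
    first sample is taken after the first gap).
    """

    n_samples: int
    swaps_per_sample: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise ValueError("n_samples must be >= 0")
        if self.swaps_per_sample is not None and self.swaps_per_sample < 1:
            raise ValueError("swaps_per_sample must be >= 1")

    def resolved_gap(self, graph: RegulationGraph) -> int:
        if self.swaps_per_sample is not None:
            return self.swaps_per_sample
        return 10 * max(1, graph.n_edges)


class _ChainState:
    """Indexed, mutable swap-chain state.

    Maintains per-type edge endpoint lists and a flat occupancy byte array
    (0 = vacant, 1 = up, 2 = down) for O(1) conflict checks.  This is the
    engine behind :func:`sample_null_graphs` and the empirical p-value
    computation; :func:`attempt_edge_swap` is the single-step reference
    implementation of the same move on a plain :class:`RegulationGraph`.
    """

    def __init__(self, graph: RegulationGraph):
        self.regulators = list(graph.regulators)
        self.targets = list(graph.targets)
        self.R = len(self.regulators)
        self.T = len(self.targets)
        self.threshold = graph.threshold
        ri = {r: i for i, r in enumerate(self.regulators)}
        ti = {t: j for j, t in enumerate(self.targets)}
        self.occ = bytearray(self.R * self.T)
        # per type: parallel lists of regulator / target indices
        self.reg_idx: dict[int, list[int]] = {_UP: [], _DOWN: []}
        self.tgt_idx: dict[int, list[int]] = {_UP: [], _DOWN: []}
        for (r, t), etype in sorted(graph.edges.items()):
            code = _UP if etype is EdgeType.UP else _DOWN
            a, b = ri[r], ti[t]
            self.occ[a * self.T + b] = code
            self.reg_idx[code].append(a)
            self.tgt_idx[code].append(b)
        self.accepted = 0
        self.attempted = 0

    def matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """Float32 biadjacency matrices ``(M_up, M_down)`` of the current state."""
        arr = np.frombuffer(bytes(self.occ), dtype=np.uint8).reshape(self.R, self.T)
        return (arr == _UP).astype(np.float32), (arr == _DOWN).astype(np.float32)

    def snapshot(self) -> RegulationGraph:
        edges: dict[tuple[str, str], EdgeType] = {}
        for code, etype in ((_UP, EdgeType.UP), (_DOWN, EdgeType.DOWN)):
            for a, b in zip(self.reg_idx[code], self.tgt_idx[code]):
                edges[(self.regulators[a], self.targets[b])] = etype
        return RegulationGraph(self.regulators, self.targets, edges, self.threshold)

    def run(self, rng: np.random.Generator, n_attempts: int, chunk: int = 1 << 16) -> int:
        """Perform ``n_attempts`` swap attempts; returns the number accepted.

        Random draws are consumed in fixed-size blocks of three uniforms per
        attempt, so the sequence of states is bit-reproducible for a given
        seeded generator regardless of acceptance outcomes.
        """
        m_up = len(self.reg_idx[_UP])
        m_down = len(self.reg_idx[_DOWN])
        m_tot = m_up + m_down  # invariant along the chain
        accepted = 0
        if m_tot == 0:
            self.attempted += n_attempts
            return 0
        p_up = m_up / m_tot
        T = self.T
        occ = self.occ
        regs_u, tgts_u = self.reg_idx[_UP], self.tgt_idx[_UP]
        regs_d, tgts_d = self.reg_idx[_DOWN], self.tgt_idx[_DOWN]
        remaining = n_attempts
        while remaining > 0:
            n = min(chunk, remaining)
            remaining -= n
            pick_up = (rng.random(n) < p_up).tolist()
            u1 = rng.random(n).tolist()
            u2 = rng.random(n).tolist()
            for is_up, x1, x2 in zip(pick_up, u1, u2):
                if is_up:
                    regs, tgts, m, code = regs_u, tgts_u, m_up, _UP
                else:
                    regs, tgts, m, code = regs_d, tgts_d, m_down, _DOWN
                if m < 2:
                    continue
                i = int(x1 * m)
                j = int(x2 * (m - 1))
                if j >= i:
                    j += 1
                a = regs[i]
                b = tgts[i]
                c = regs[j]
                d = tgts[j]
                if occ[a * T + d] or occ[c * T + b]:
                    continue
                occ[a * T + b] = 0
                occ[c * T + d] = 0
                occ[a * T + d] = code
                occ[c * T + b] = code
                tgts[i] = d
                tgts[j] = b
                accepted += 1
        self.attempted += n_attempts
        self.accepted += accepted
        return accepted


def attempt_edge_swap(G: RegulationGraph, rng: np.random.Generator) -> str:
    """Attempt one same-type edge swap on ``G`` in place.

    Returns ``"swapped"`` or ``"rejected"``.  The per-type degree signature of
    every node is identical before and after.  Fewer than two edges of the
    drawn type is a rejection, not an error.
    """
    ups = sorted(G.edges_of_type(EdgeType.UP))
    downs = sorted(G.edges_of_type(EdgeType.DOWN))
    m_tot = len(ups) + len(downs)
    if m_tot == 0:
        return "rejected"
    if rng.random() < len(ups) / m_tot:
        pool, etype = ups, EdgeType.UP
    else:
        pool, etype = downs, EdgeType.DOWN
    m = len(pool)
    if m < 2:
        return "rejected"
    i = int(rng.random() * m)
    j = int(rng.random() * (m - 1))
    if j >= i:
        j += 1
    (a, b), (c, d) = pool[i], pool[j]
    if (a, d) in G.edges or (c, b) in G.edges:
        return "rejected"
    del G.edges[(a, b)]
    del G.edges[(c, d)]
    G.edges[(a, d)] = etype
    G.edges[(c, b)] = etype
    return "swapped"


def sample_null_graphs(G: RegulationGraph, cfg: SwapChainConfig) -> Iterator[RegulationGraph]:
    """Lazily yield ``cfg.n_samples`` null graphs along one continuing chain.

    The chain starts at the observed graph; a state is emitted every
    ``swaps_per_sample`` attempted swaps.  Every yielded graph has exactly the
    per-type degree signature of ``G``; identical ``cfg`` (including seed)
    yields an identical sequence.
    """
    state = _ChainState(G)
    rng = np.random.default_rng(cfg.seed)
    gap = cfg.resolved_gap(G)
    for _ in range(cfg.n_samples):
        state.run(rng, gap)
        yield state.snapshot()
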