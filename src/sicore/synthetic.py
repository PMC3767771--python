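"""Modular artificial regulation graphs with a built-in gold standard.

The benchmark emulates the structure of a genome-scale regulator x readout
screen: a strong side imbalance (many more regulators than targets), a
strongly skewed regulator degree distribution (a few hubs, many degree-2
nodes), a half-up / half-down split of each regulator's edges, and planted
co-regulation modules.  Each module contains a group of up-regulated and a
group of down-regulated targets wired to that module's regulators only, so
the intended result of a projection is known by construction:

* every pair within an up-group is a co-up positive;
* every pair within a down-group is a co-down positive;
* every ordered (down-group member, up-group member) pair within a module is
  an antagonistic positive, directed from the down- to the up-regulated node;
* everything else, including all cross-module pairs, is negative.

Target degrees are emergent (approximately Poisson, since endpoints are drawn
uniformly within a group).  With the default configuration the negative class
outweighs the positive one roughly 20-fold for each pattern.  Two noise
operations model false negatives (random edge deletion) and false positives
(random edge addition).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .graph import EdgeType, RegulationGraph
from .projection import Pattern

#: Per-module regulator degree histogram as (degree, count) pairs.  Strongly
#: skewed: 10 hubs that reach every target of the module, 8 mid-degree nodes,
#: 40 degree-2 nodes.  The hub redundancy guarantees that every planted pair
#: co-occurs at least 10 times, far in the tail of the degree-preserving null.
DEFAULT_REGULATOR_DEGREES: tuple[tuple[int, int], ...] = ((16, 10), (4, 8), (2, 40))


@dataclass(frozen=True)
class ArtificialConfig:
    """Structural parameters of the artificial graphs.

    ``regulator_degrees`` lists (degree, count) pairs per module.  Each
    regulator's edges are split half up (into the module's up-group) and half
    down (into the down-group); for odd degrees the extra edge's type
    alternates deterministically across regulators.
    """

    n_modules: int = 5
    n_up_targets: int = 8
    n_down_targets: int = 8
    regulator_degrees: tuple[tuple[int, int], ...] = DEFAULT_REGULATOR_DEGREES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules < 1 or self.n_up_targets < 1 or self.n_down_targets < 1:
            raise ValueError("module and group counts must be positive")
        for degree, count in self.regulator_degrees:
            if degree < 1 or count < 1:
                raise ValueError("regulator degree spec entries must be positive")
            half = (degree + 1) // 2
            if half > self.n_up_targets or half > self.n_down_targets:
                raise ValueError(
                    f"regulator degree {degree} needs {half} distinct partners per "
                    f"group but groups have only {self.n_up_targets} up / "
                    f"{self.n_down_targets} down targets"
                )

    @property
    def regulators_per_module(self) -> int:
        return sum(c for _, c in self.regulator_degrees)

    @property
    def edges_per_module(self) -> int:
        return sum(d * c for d, c in self.regulator_degrees)


@dataclass(frozen=True)
class GoldStandard:
    """Positive pair sets implied by the artificial construction.

    Depends only on the structural configuration, not on the RNG seed.
    Symmetric positives are stored as node-order-sorted tuples, antagonistic
    positives as ordered (down-group member, up-group member) tuples.
    """

    nodes: tuple[str, ...]
    co_up: frozenset[tuple[str, str]]
    co_down: frozenset[tuple[str, str]]
    antagonistic: frozenset[tuple[str, str]]

    def positives(self, pattern: Pattern) -> frozenset[tuple[str, str]]:
        return {
            Pattern.CO_UP: self.co_up,
            Pattern.CO_DOWN: self.co_down,
            Pattern.ANTAGONISTIC: self.antagonistic,
        }[Pattern(pattern)]

    def universe_size(self, pattern: Pattern) -> int:
        n = len(self.nodes)
        return n * (n - 1) // 2 if Pattern(pattern).symmetric else n * (n - 1)

    def n_negatives(self, pattern: Pattern) -> int:
        return self.universe_size(pattern) - len(self.positives(pattern))

    def imbalance(self, pattern: Pattern) -> float:
        """Negative : positive pair ratio (the class imbalance)."""
        return self.n_negatives(pattern) / len(self.positives(pattern))

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("pattern\tnode_a\tnode_b\n")
            for pattern in Pattern:
                for a, b in sorted(self.positives(pattern)):
                    fh.write(f"{pattern.value}\t{a}\t{b}\n")

    @classmethod
    def read_tsv(cls, path, nodes: Iterable[str]) -> "GoldStandard":
        sets: dict[Pattern, set[tuple[str, str]]] = {p: set() for p in Pattern}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:3] != ["pattern", "node_a", "node_b"]:
                raise ValueError(f"unexpected gold-standard header: {header}")
            for line in fh:
                if not line.strip():
                    continue
                pat, a, b = line.rstrip("\n").split("\t")[:3]
                sets[Pattern(pat)].add((a, b))
        return cls(tuple(nodes), frozenset(sets[Pattern.CO_UP]),
                   frozenset(sets[Pattern.CO_DOWN]),
                   frozenset(sets[Pattern.ANTAGONISTIC]))


def _module_labels(cfg: ArtificialConfig, m: int):
    up = [f"prot_m{m:02d}_up{i:02d}" for i in range(cfg.n_up_targets)]
    down = [f"prot_m{m:02d}_dn{i:02d}" for i in range(cfg.n_down_targets)]
    regs = [f"mir_m{m:02d}_{i:03d}" for i in range(cfg.regulators_per_module)]
    return regs, up, down


def gold_standard_for(cfg: ArtificialConfig) -> GoldStandard:
    """Gold standard for a configuration; independent of the seed."""
    co_up: set[tuple[str, str]] = set()
    co_down: set[tuple[str, str]] = set()
    ant: set[tuple[str, str]] = set()
    nodes: list[str] = []
    for m in range(cfg.n_modules):
        _, up, down = _module_labels(cfg, m)
        nodes.extend(up)
        nodes.extend(down)
        co_up.update((a, b) for i, a in enumerate(up) for b in up[i + 1:])
        co_down.update((a, b) for i, a in enumerate(down) for b in down[i + 1:])
        ant.update((d, u) for d in down for u in up)
    return GoldStandard(tuple(nodes), frozenset(co_up), frozenset(co_down),
                        frozenset(ant))


def generate_artificial_graph(cfg: ArtificialConfig) -> tuple[RegulationGraph, GoldStandard]:
    """Generate one artificial regulation graph plus its gold standard.

    Modules are generated independently; within a module each regulator's up
    (down) partners are drawn uniformly without replacement from the module's
    up (down) group.  Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    regulators: list[str] = []
    targets: list[str] = []
    edges: dict[tuple[str, str], EdgeType] = {}
    odd_extra_up = True  # alternates across odd-degree regulators
    for m in range(cfg.n_modules):
        regs, up_group, down_group = _module_labels(cfg, m)
        regulators.extend(regs)
        targets.extend(up_group)
        targets.extend(down_group)
        degrees = [d for d, c in cfg.regulator_degrees for _ in range(c)]
        for reg, degree in zip(regs, degrees):
            n_up = degree // 2
            n_down = degree - n_up
            if degree % 2:
                if odd_extra_up:
                    n_up, n_down = n_down, n_up
                odd_extra_up = not odd_extra_up
            for t_idx in rng.choice(cfg.n_up_targets, size=n_up, replace=False):
                edges[(reg, up_group[t_idx])] = EdgeType.UP
            for t_idx in rng.choice(cfg.n_down_targets, size=n_down, replace=False):
                edges[(reg, down_group[t_idx])] = EdgeType.DOWN
    graph = RegulationGraph(regulators, targets, edges, threshold="synthetic")
    return graph, gold_standard_for(cfg)


def delete_edges(G: RegulationGraph, p: float,
                 rng: np.random.Generator) -> RegulationGraph:
    """Remove ``round(p/100 * |E|)`` uniformly chosen edges (nodes kept).

    Models false-negative observations.  Rounding is round-half-to-even.
    Returns a new graph; the input is untouched.
    """
    if not 0.0 <= p <= 100.0:
        raise ValueError(f"deletion percentage must be in [0, 100], got {p}")
    n_remove = round(p / 100.0 * G.n_edges)
    pairs = sorted(G.edges)
    drop = {pairs[i] for i in rng.choice(len(pairs), size=n_remove, replace=False)} \
        if n_remove else set()
    kept = {pair: e for pair, e in G.edges.items() if pair not in drop}
    return RegulationGraph(G.regulators, G.targets, kept, G.threshold)


def add_edges(G: RegulationGraph, p: float, rng: np.random.Generator,
              up_probability: float = 0.5) -> RegulationGraph:
    """Add ``round(p/100 * |E|)`` edges into uniformly chosen vacant slots.

    Models false-positive observations.  Each added edge is typed UP with
    probability ``up_probability`` (fair coin by default; real screens skew
    towards down-regulation, which the knob can emulate).  Raises if the
    requested number exceeds the vacant (regulator, target) slots.
    """
    if p < 0.0:
        raise ValueError(f"addition percentage must be >= 0, got {p}")
    if not 0.0 <= up_probability <= 1.0:
        raise ValueError("up_probability must be in [0, 1]")
    n_add = round(p / 100.0 * G.n_edges)
    vacant = [(r, t) for r in G.regulators for t in G.targets
              if (r, t) not in G.edges]
    if n_add > len(vacant):
        raise ValueError(
            f"cannot add {n_add} edges: only {len(vacant)} vacant slots"
        )
    edges = dict(G.edges)
    if n_add:
        picks = rng.choice(len(vacant), size=n_add, replace=False)
        types = rng.random(n_add) < up_probability
        for k, is_up in zip(picks.tolist(), types.tolist()):
            edges[vacant[k]] = EdgeType.UP if is_up else EdgeType.DOWN
    return RegulationGraph(G.regulators, G.targets, edges, G.threshold)
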