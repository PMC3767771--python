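"""Internal-reference selection of the projection threshold.

Rather than fixing the projection significance threshold by rule of thumb,
the topology of the projection is traced over a grid of candidate thresholds
and structurally informative values are flagged: thresholds where the
clustering coefficient and the component density jump or peak while the graph
still decomposes into a fair number of components.  The scan table is always
emitted in full; the automated suggestions are advisory and never silently
pick the final threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .projection import PairStatTable, Pattern

SCAN_COLUMNS = [
    "tau", "n_edges", "n_edges_norm", "n_components",
    "component_density", "component_density_norm", "clustering",
]


def _subgraph_at(stats: PairStatTable, pattern: Pattern, tau: float) -> nx.Graph:
    pairs, obs, p = stats.candidate_arrays(pattern)
    keep = (obs >= 1) & (p <= tau)
    g = nx.Graph()
    for k in np.flatnonzero(keep):
        g.add_edge(*pairs[k])
    return g


def scan_projection_thresholds(stats: PairStatTable, pattern: Pattern,
                               grid) -> pd.DataFrame:
    """Four topology metrics of the pattern's projection along a tau grid.

    Per grid value the projection subgraph (antagonistic direction ignored)
    is built and the following are computed: edge count normalized to the
    grid maximum; number of connected components with >= 2 nodes; mean
    per-component density (edges / C(size, 2)), both raw and normalized to
    its grid maximum; and the average local clustering coefficient (nodes of
    degree < 2 contribute 0).  An empty projection yields an all-zero row.
    """
    grid = [float(t) for t in grid]
    if not grid:
        raise ValueError("grid must be nonempty")
    if any(not 0.0 <= t <= 1.0 for t in grid):
        raise ValueError("grid values must lie in [0, 1]")
    if sorted(grid) != grid:
        raise ValueError("grid must be increasing")
    rows = []
    for tau in grid:
        g = _subgraph_at(stats, pattern, tau)
        n_edges = g.number_of_edges()
        if n_edges == 0:
            rows.append({"tau": tau, "n_edges": 0, "n_components": 0,
                         "component_density": 0.0, "clustering": 0.0})
            continue
        comps = [c for c in nx.connected_components(g) if len(c) >= 2]
        densities = [
            g.subgraph(c).number_of_edges() / (len(c) * (len(c) - 1) / 2)
            for c in comps
        ]
        rows.append({
            "tau": tau,
            "n_edges": n_edges,
            "n_components": len(comps),
            "component_density": float(np.mean(densities)) if densities else 0.0,
            "clustering": float(nx.average_clustering(g)),
        })
    df = pd.DataFrame(rows)
    max_edges = df["n_edges"].max()
    df["n_edges_norm"] = df["n_edges"] / max_edges if max_edges > 0 else 0.0
    max_dens = df["component_density"].max()
    df["component_density_norm"] = (
        df["component_density"] / max_dens if max_dens > 0 else 0.0
    )
    return df[SCAN_COLUMNS]


@dataclass(frozen=True)
class ThresholdCandidate:
    tau: float
    reasons: tuple[str, ...]
    score: float


def _local_maxima(v: np.ndarray) -> np.ndarray:
    """Strict-on-one-side local maxima, endpoints included."""
    n = len(v)
    out = np.zeros(n, dtype=bool)
    for i in range(n):
        left = v[i - 1] if i > 0 else None
        right = v[i + 1] if i < n - 1 else None
        ge = all(x is None or v[i] >= x for x in (left, right))
        gt = any(x is not None and v[i] > x for x in (left, right))
        out[i] = ge and gt
    return out


def _strong_increases(v: np.ndarray, quantile: float) -> np.ndarray:
    """Grid points whose backward forward-difference is unusually large."""
    n = len(v)
    out = np.zeros(n, dtype=bool)
    diffs = np.diff(v)
    if len(diffs) == 0:
        return out
    cutoff = float(np.quantile(diffs, quantile))
    for i in range(1, n):
        d = diffs[i - 1]
        out[i] = d > 0 and d >= cutoff
    return out


def suggest_thresholds(rows: pd.DataFrame, top_k: int = 3,
                       diff_quantile: float = 0.75,
                       min_components: int = 5) -> list[ThresholdCandidate]:
    """Flag tau values where the topology signals structure.

    A grid point is a candidate when *both* the clustering coefficient and
    the normalized component density show a local maximum or a forward
    difference at or above ``diff_quantile`` of that metric's differences,
    while the number of components is at least ``min_components``.  Up to
    ``top_k`` candidates are returned, ranked by the sum of the two metric
    values (ties: smaller tau first), each annotated with the criteria that
    fired.  Deterministic; constant curves yield no candidates.
    """
    if len(rows) < 3:
        raise ValueError("need at least 3 scan rows")
    taus = rows["tau"].to_numpy(dtype=float)
    metrics = {
        "clustering": rows["clustering"].to_numpy(dtype=float),
        "component_density": rows["component_density_norm"].to_numpy(dtype=float),
    }
    fired: dict[str, list[str]] = {}
    per_metric_ok = []
    reasons_at = [[] for _ in taus]
    for name, v in metrics.items():
        lm = _local_maxima(v)
        si = _strong_increases(v, diff_quantile)
        per_metric_ok.append(lm | si)
        for i in range(len(taus)):
            if lm[i]:
                reasons_at[i].append(f"{name}:local_max")
            if si[i]:
                reasons_at[i].append(f"{name}:strong_increase")
    ok = per_metric_ok[0] & per_metric_ok[1]
    ok &= rows["n_components"].to_numpy() >= min_components
    candidates = [
        ThresholdCandidate(
            tau=float(taus[i]),
            reasons=tuple(reasons_at[i]),
            score=float(metrics["clustering"][i] + metrics["component_density"][i]),
        )
        for i in np.flatnonzero(ok)
    ]
    candidates.sort(key=lambda c: (-c.score, c.tau))
    return candidates[:top_k]
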