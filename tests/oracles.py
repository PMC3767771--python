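"""Independent oracles used by the tests.

Everything here is deliberately brute-force and written without reference to
the package internals: exhaustive enumeration of typed bipartite graphs with
fixed per-type degree signatures, naive co-occurrence counting, and a full
dynamic-programming edit distance.
"""

from __future__ import annotations

from itertools import combinations


def enumerate_typed_graphs(reg_sig: dict[str, tuple[int, int]],
                           tgt_sig: dict[str, tuple[int, int]]) -> list[frozenset]:
    """All simple bipartite graphs with the given (up, down) degree signatures.

    Returns canonical edge sets ``frozenset((reg, tgt, "up"/"down"))``.
    Backtracks regulator by regulator, assigning up-partners then
    down-partners among the remaining capacity; a pair carries at most one
    edge of either type.
    """
    regs = sorted(reg_sig)
    tgts = sorted(tgt_sig)
    up_cap = {t: tgt_sig[t][0] for t in tgts}
    down_cap = {t: tgt_sig[t][1] for t in tgts}
    results: list[frozenset] = []
    edges: list[tuple[str, str, str]] = []

    def place(i: int) -> None:
        if i == len(regs):
            if all(v == 0 for v in up_cap.values()) and \
               all(v == 0 for v in down_cap.values()):
                results.append(frozenset(edges))
            return
        r = regs[i]
        n_up, n_down = reg_sig[r]
        up_avail = [t for t in tgts if up_cap[t] > 0]
        for ups in combinations(up_avail, n_up):
            for t in ups:
                up_cap[t] -= 1
            down_avail = [t for t in tgts if down_cap[t] > 0 and t not in ups]
            for downs in combinations(down_avail, n_down):
                for t in downs:
                    down_cap[t] -= 1
                edges.extend((r, t, "up") for t in ups)
                edges.extend((r, t, "down") for t in downs)
                place(i + 1)
                del edges[len(edges) - n_up - n_down:]
                for t in downs:
                    down_cap[t] += 1
            for t in ups:
                up_cap[t] += 1

    place(0)
    return results


def count_pattern(edge_set: frozenset, side: str, a: str, b: str,
                  pattern: str) -> int:
    """Naive co-occurrence count of one pair in one canonical edge set.

    ``pattern`` is ``"co_up"``, ``"co_down"`` or ``"antagonistic"``; for the
    antagonistic pattern the pair is ordered ``(a, b)`` with ``a`` the
    down-linked member.
    """
    def neighbours(node: str, etype: str) -> set[str]:
        if side == "target":
            return {r for (r, t, e) in edge_set if t == node and e == etype}
        return {t for (r, t, e) in edge_set if r == node and e == etype}

    if pattern == "co_up":
        return len(neighbours(a, "up") & neighbours(b, "up"))
    if pattern == "co_down":
        return len(neighbours(a, "down") & neighbours(b, "down"))
    return len(neighbours(a, "down") & neighbours(b, "up"))


def exact_exceed_probability(graphs: list[frozenset], side: str, a: str,
                             b: str, pattern: str, observed: int) -> float:
    """P(count >= observed) under the uniform distribution over ``graphs``."""
    hits = sum(1 for g in graphs
               if count_pattern(g, side, a, b, pattern) >= observed)
    return hits / len(graphs)


def dp_edit_distance(s1: str, s2: str) -> int:
    """Full-matrix Wagner-Fischer Levenshtein distance."""
    m, n = len(s1), len(s2)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cost = 0 if s1[i - 1] == s2[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
        prev = cur
    return prev[n]


def swap_neighbours(edge_set: frozenset) -> list[frozenset]:
    """All edge sets reachable from ``edge_set`` by one accepted swap."""
    occupied = {(r, t) for (r, t, _) in edge_set}
    by_type: dict[str, list] = {"up": [], "down": []}
    for r, t, e in edge_set:
        by_type[e].append((r, t))
    out = []
    for etype, edges in by_type.items():
        for (a, b), (c, d) in combinations(sorted(edges), 2):
            if (a, d) in occupied or (c, b) in occupied:
                continue
            out.append(frozenset(
                (edge_set - {(a, b, etype), (c, d, etype)})
                | {(a, d, etype), (c, b, etype)}))
    return out


def swap_reachable_component(start: frozenset) -> set[frozenset]:
    """The swap chain's communicating class containing ``start``.

    With two edge types and the cross-type conflict rule the chain is not
    guaranteed to connect the full degree-compatible state space; its
    stationary distribution is uniform on this component.
    """
    seen = {start}
    frontier = [start]
    while frontier:
        nxt = []
        for state in frontier:
            for nb in swap_neighbours(state):
                if nb not in seen:
                    seen.add(nb)
                    nxt.append(nb)
        frontier = nxt
    return seen
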