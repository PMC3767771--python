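import math

import numpy as np
import pytest

import sicore as sc
from conftest import random_regulation_graph
from oracles import (enumerate_typed_graphs, exact_exceed_probability,
                     swap_reachable_component)

UP, DOWN = sc.EdgeType.UP, sc.EdgeType.DOWN


def pair_stat(stats, pattern, a, b):
    i, j = stats.nodes.index(a), stats.nodes.index(b)
    obs = stats.observed_matrix(pattern)[i, j]
    p = stats.p_emp_matrix(pattern)[i, j] if stats.has_pvalues else None
    return int(obs), p


class TestCountCooccurrences:
    def test_antagonistic_direction_points_from_down_to_up(self):
        # miRNA A down-regulates p, miRNA B up-regulates p
        G = sc.RegulationGraph(["A", "B"], ["p"],
                               {("A", "p"): DOWN, ("B", "p"): UP})
        stats = sc.count_cooccurrences(G, "regulator")
        ant = stats.observed_matrix(sc.Pattern.ANTAGONISTIC)
        i, j = stats.nodes.index("A"), stats.nodes.index("B")
        assert ant[i, j] == 1 and ant[j, i] == 0

    def test_empty_graph_counts_are_zero(self):
        G = sc.RegulationGraph(["r"], ["t"], {})
        stats = sc.count_cooccurrences(G, "target")
        for p in sc.Pattern:
            assert stats.observed_matrix(p).sum() == 0

    def test_shared_up_regulators_are_counted(self):
        G = sc.RegulationGraph(["m1", "m2"], ["P1", "P2"],
                               {("m1", "P1"): UP, ("m1", "P2"): UP,
                                ("m2", "P1"): UP, ("m2", "P2"): UP})
        stats = sc.count_cooccurrences(G, "target")
        obs, _ = pair_stat(stats, sc.Pattern.CO_UP, "P1", "P2")
        assert obs == 2

    def test_symmetric_patterns_are_symmetric(self):
        rng = np.random.default_rng(0)
        G = random_regulation_graph(rng)
        stats = sc.count_cooccurrences(G, "target")
        for p in (sc.Pattern.CO_UP, sc.Pattern.CO_DOWN):
            m = stats.observed_matrix(p)
            np.testing.assert_array_equal(m, m.T)

    @pytest.mark.parametrize("seed", range(4))
    def test_count_conservation(self, seed):
        # total co-up pair incidences = sum over regulators of C(up_deg, 2)
        rng = np.random.default_rng(seed)
        G = random_regulation_graph(rng, n_reg=15, n_tgt=9, density=0.35)
        stats = sc.count_cooccurrences(G, "target")
        m = stats.observed_matrix(sc.Pattern.CO_UP)
        total = int(np.triu(m, 1).sum())
        expected = sum(math.comb(u, 2)
                       for u, _ in G.degree_signature("regulator").values())
        assert total == expected


class TestEmpiricalPvalues:
    def test_zero_count_pairs_get_p_one(self, hub_instance):
        stats = sc.empirical_pvalues(hub_instance, "target",
                                     sc.SwapChainConfig(50, 20, seed=0))
        obs, p = pair_stat(stats, sc.Pattern.CO_UP, "p2", "p3")
        assert obs == 0 and p == 1.0

    def test_hub_pair_pvalue_matches_enumeration(self, hub_instance):
        # exact P(count >= 1) = 2/5 over the 5-graph state space
        stats = sc.empirical_pvalues(hub_instance, "target",
                                     sc.SwapChainConfig(10_000, 20, seed=1))
        obs, p = pair_stat(stats, sc.Pattern.CO_UP, "p1", "p2")
        assert obs == 1
        assert p == pytest.approx(0.4, abs=0.015)

    def test_rigid_degree_sequence_gives_all_p_one(self):
        # complete bipartite in one type admits exactly one graph
        G = sc.RegulationGraph(["r1", "r2"], ["t1", "t2"],
                               {(r, t): UP for r in ("r1", "r2")
                                for t in ("t1", "t2")})
        stats = sc.empirical_pvalues(G, "target",
                                     sc.SwapChainConfig(200, 10, seed=2))
        assert (stats.p_emp_matrix(sc.Pattern.CO_UP) == 1.0).all()

    def test_reproducible_for_fixed_seed(self, hub_instance):
        cfg = sc.SwapChainConfig(500, 20, seed=3)
        s1 = sc.empirical_pvalues(hub_instance, "target", cfg)
        s2 = sc.empirical_pvalues(hub_instance, "target", cfg)
        for p in sc.Pattern:
            np.testing.assert_array_equal(s1.exceed[p], s2.exceed[p])

    @pytest.mark.parametrize("side", ["target", "regulator"])
    def test_agreement_with_enumeration_oracle(self, side):
        # mixed-type instance with <= 8 edges: every pair/pattern estimate
        # within 3 binomial standard errors of the exact probability under
        # the uniform distribution on the chain's communicating class
        edges = {("r1", "t1"): UP, ("r1", "t2"): UP, ("r2", "t1"): UP,
                 ("r2", "t3"): DOWN, ("r3", "t2"): DOWN, ("r3", "t3"): UP}
        G = sc.RegulationGraph(["r1", "r2", "r3"], ["t1", "t2", "t3"], edges)
        space = sorted(swap_reachable_component(G.canonical_edges()))
        full = enumerate_typed_graphs(dict(G.degree_signature("regulator")),
                                      dict(G.degree_signature("target")))
        assert set(space) <= set(full)
        n = 4000
        stats = sc.empirical_pvalues(G, side, sc.SwapChainConfig(n, 60, seed=4))
        for pattern in sc.Pattern:
            pairs, obs, p_emp = stats.candidate_arrays(pattern)
            for (a, b), o, p in zip(pairs, obs, p_emp):
                if o == 0:
                    continue
                exact = exact_exceed_probability(space, side, a, b,
                                                 pattern.value, int(o))
                se = math.sqrt(exact * (1 - exact) / n)
                assert abs(p - exact) <= max(3 * se, 1e-9), \
                    (pattern, a, b, p, exact)


class TestCoRegulationGraph:
    def test_tau_one_keeps_every_cooccurring_pair(self, hub_instance):
        stats = sc.empirical_pvalues(hub_instance, "target",
                                     sc.SwapChainConfig(100, 20, seed=5))
        C = sc.build_coregulation_graph(stats, 1.0)
        assert C.pattern_pairs(sc.Pattern.CO_UP) == {("p1", "p2")}

    def test_exact_p_04_pair_excluded_at_tau_03(self, hub_instance):
        stats = sc.empirical_pvalues(hub_instance, "target",
                                     sc.SwapChainConfig(10_000, 20, seed=6))
        C = sc.build_coregulation_graph(stats, 0.3)
        assert C.pattern_pairs(sc.Pattern.CO_UP) == set()

    def test_filter_nesting(self):
        rng = np.random.default_rng(9)
        G = random_regulation_graph(rng, n_reg=15, n_tgt=10, density=0.3)
        stats = sc.empirical_pvalues(G, "target", sc.SwapChainConfig(200, seed=7))
        taus = [0.0, 0.05, 0.2, 0.5, 1.0]
        previous = None
        for tau in taus:
            C = sc.build_coregulation_graph(stats, tau)
            current = {p: C.pattern_pairs(p) for p in sc.Pattern}
            if previous is not None:
                for p in sc.Pattern:
                    assert previous[p] <= current[p]
            previous = current

    @pytest.mark.parametrize("tau", [-0.1, 1.1])
    def test_invalid_tau_rejected(self, hub_instance, tau):
        stats = sc.empirical_pvalues(hub_instance, "target",
                                     sc.SwapChainConfig(10, 20, seed=8))
        with pytest.raises(ValueError):
            sc.build_coregulation_graph(stats, tau)


class TestConnectedGroups:
    def make_projection(self, pairs):
        nodes = sorted({x for pair in pairs for x in pair} | {"E"})
        edges = {sc.Pattern.CO_UP: {pair: (1, 0.0) for pair in pairs}}
        return sc.CoRegulationGraph("target", nodes, 0.05, edges)

    def test_components_of_min_size(self):
        C = self.make_projection([("A", "B"), ("C", "D")])
        assert sc.connected_groups(C, sc.Pattern.CO_UP, 2) == [["A", "B"],
                                                               ["C", "D"]]

    def test_empty_projection(self):
        C = self.make_projection([])
        assert sc.connected_groups(C, sc.Pattern.CO_UP, 2) == []

    def test_min_size_larger_than_any_component(self):
        C = self.make_projection([("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")])
        assert sc.connected_groups(C, sc.Pattern.CO_UP, 6) == []

    def test_ordering_descending_size_then_lexicographic(self):
        C = self.make_projection([("X", "Y"), ("A", "B"), ("B", "C")])
        assert sc.connected_groups(C, sc.Pattern.CO_UP, 2) == [
            ["A", "B", "C"], ["X", "Y"]]


class TestPairStatTableIO:
    def test_tsv_round_trip(self, tmp_path, hub_instance):
        stats = sc.empirical_pvalues(hub_instance, "target",
                                     sc.SwapChainConfig(100, 20, seed=9))
        stats.to_tsv(tmp_path / "run")
        back = sc.PairStatTable.from_tsv(tmp_path / "run")
        assert back.nodes == stats.nodes and back.side == stats.side
        for p in sc.Pattern:
            np.testing.assert_array_equal(back.observed[p], stats.observed[p])
            np.testing.assert_array_equal(back.exceed[p], stats.exceed[p])
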