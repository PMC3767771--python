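import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sicore as sc

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def tiny_matrix():
    """The 2x2 demo matrix used across modules."""
    return sc.ZScoreMatrix(["r1", "r2"], ["t1", "t2"],
                           np.array([[1.7, -0.3], [-2.1, 1.5]]))


@pytest.fixture
def hub_instance():
    """Single-type instance with degrees (2,1,1) on both sides.

    Observed graph: p1-{m1,m2}, p2-m1, p3-m3.  Its state space (all graphs
    with the same degree sequences) has exactly 5 members and the hub pair
    (p1, p2) shares a neighbour in 2 of them.
    """
    edges = {("m1", "p1"): sc.EdgeType.UP, ("m2", "p1"): sc.EdgeType.UP,
             ("m1", "p2"): sc.EdgeType.UP, ("m3", "p3"): sc.EdgeType.UP}
    return sc.RegulationGraph(["m1", "m2", "m3"], ["p1", "p2", "p3"], edges)


def random_regulation_graph(rng, n_reg=12, n_tgt=8, density=0.3):
    """Random typed bipartite graph for property tests."""
    regs = [f"r{i}" for i in range(n_reg)]
    tgts = [f"t{j}" for j in range(n_tgt)]
    edges = {}
    for r in regs:
        for t in tgts:
            u = rng.random()
            if u < density / 2:
                edges[(r, t)] = sc.EdgeType.UP
            elif u < density:
                edges[(r, t)] = sc.EdgeType.DOWN
    return sc.RegulationGraph(regs, tgts, edges)


@pytest.fixture(scope="session")
def default_benchmark():
    """Pristine default artificial graph and its gold standard."""
    return sc.generate_artificial_graph(sc.ArtificialConfig(seed=42))


@pytest.fixture(scope="session")
def zero_noise_stats(default_benchmark):
    """Target-side empirical p-values on the pristine benchmark, N = 1000."""
    graph, _ = default_benchmark
    return sc.empirical_pvalues(graph, sc.SIDE_TARGET,
                                sc.SwapChainConfig(n_samples=1000, seed=43))


@pytest.fixture(scope="session")
def noisy_benchmark_stats(default_benchmark):
    """Half the edges deleted, then projected; used for scan/threshold tests."""
    graph, gold = default_benchmark
    noisy = sc.delete_edges(graph, 50, np.random.default_rng(7))
    stats = sc.empirical_pvalues(noisy, sc.SIDE_TARGET,
                                 sc.SwapChainConfig(n_samples=500, seed=8))
    return stats, gold
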