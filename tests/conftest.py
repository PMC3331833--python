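import networkx as nx
import pytest

from polyq_netscreen.synthetic import SyntheticTruth, simulate_network, simulate_smooth_signal


@pytest.fixture(scope="session")
def small_truth() -> SyntheticTruth:
    """Desk-scale study: 60 genes, two planted 6-gene modules at +/-2 SD."""
    return SyntheticTruth(
        n_genes=60,
        module_sizes=(6, 6),
        module_effects_sd=(2.0, -2.0),
        p_in=0.8,
        p_out=0.02,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_network(small_truth) -> nx.Graph:
    return simulate_network(small_truth)


@pytest.fixture(scope="session")
def small_signal(small_truth):
    noisy, clean = simulate_smooth_signal(small_truth)
    return noisy


@pytest.fixture
def triangle() -> nx.Graph:
    g = nx.Graph()
    g.add_weighted_edges_from([("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0)])
    return g
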