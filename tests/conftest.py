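import numpy as np
import pytest

import netpharm as nh


@pytest.fixture(scope="session")
def small_cfg() -> nh.ScenarioConfig:
    """A reduced scenario for fast structural tests."""
    return nh.ScenarioConfig(
        n_genes=120,
        n_disease_genes=20,
        n_drug_affected=20,
        n_network_nodes=120,
        n_planted_hubs=5,
        hub_extra_edges=10,
        n_pathways=8,
        pathway_size_range=(8, 15),
        n_compounds=12,
        fingerprint_length=256,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_scenario(small_cfg):
    """All artifacts of the reduced scenario (shared, read-only)."""
    return nh.simulate_all(small_cfg)


@pytest.fixture(scope="session")
def default_scenario():
    """One default-condition scenario (shared, read-only)."""
    return nh.simulate_all(nh.ScenarioConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_graph_edges(rng, max_nodes: int = 12):
    """A random simple graph as (edge list, node list); may be disconnected."""
    n = int(rng.integers(2, max_nodes + 1))
    nodes = [f"n{i:02d}" for i in range(n)]
    p = float(rng.uniform(0.1, 0.6))
    edges = [
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return edges, nodes
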