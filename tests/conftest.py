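import networkx as nx
import numpy as np
import pytest

from herbnet.synthdata import SynthConfig


@pytest.fixture
def small_config() -> SynthConfig:
    """Desk-scale config: fast, every planted structure still present."""
    return SynthConfig(
        seed=7,
        n_herbs=4,
        n_compounds=100,
        pass_fraction=0.2,
        n_whitelisted=5,
        n_targets=40,
        n_ct_edges=120,
        interactome_nodes=150,
        planted_module_size=20,
        planted_module_density=0.9,
        n_disease_genes=50,
        disease_overlap=0.2,
        disease_target_overlap=0.3,
        n_terms=12,
        planted_term_enrichment=40.0,
    )


@pytest.fixture
def k4() -> nx.Graph:
    return nx.complete_graph(4)


def random_graph(rng: np.random.Generator, max_n: int = 12, ensure_edge: bool = True) -> nx.Graph:
    """A small G(n, p) with at least one edge (for eigenvector centrality)."""
    while True:
        n = int(rng.integers(2, max_n + 1))
        p = float(rng.uniform(0.15, 0.9))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if g.number_of_edges() >= 1 or not ensure_edge:
            return g
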