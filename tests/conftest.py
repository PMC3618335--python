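import networkx as nx
import numpy as np
import pytest

import coexnet as cx
from coexnet.network import GeneNetwork


def graph_from_nx(g: nx.Graph) -> GeneNetwork:
    return GeneNetwork([str(n) for n in g.nodes], [(str(a), str(b)) for a, b in g.edges])


@pytest.fixture(scope="session")
def small_truth():
    """Planted GGM with 3 modules of 10 genes (study defaults, small p)."""
    return cx.make_precision_matrix(p=30, module_sizes=[10, 10, 10], seed=0)


@pytest.fixture(scope="session")
def small_study(small_truth):
    """Expression + phenotype drawn from the small planted model, n=56."""
    expr = cx.sample_expression(small_truth, n=56, seed=1)
    pheno = cx.attach_phenotype(expr, small_truth, effect_size=1.0, noise_sd=0.2, seed=2)
    return small_truth, expr, pheno


def random_connected_graph(n: int, rng: np.random.Generator, p_edge: float = 0.4):
    """Random connected simple graph used by brute-force oracles."""
    while True:
        g = nx.gnp_random_graph(n, p_edge, seed=int(rng.integers(2**31)))
        if g.number_of_edges() and nx.is_connected(g):
            return graph_from_nx(g)


def two_cliques(k: int = 5) -> GeneNetwork:
    """Two k-cliques joined by a single bridge edge."""
    g = nx.disjoint_union(nx.complete_graph(k), nx.complete_graph(k))
    g.add_edge(0, k)
    return graph_from_nx(g)
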