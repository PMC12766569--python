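import numpy as np
import pytest

from editrace.matrix import CharacterMatrix
from editrace.simulate import SimulationConfig, simulate_experiment
from editrace.tree import LineageTree


@pytest.fixture(scope="session")
def small_experiment():
    """50-cell simulated experiment with full detection."""
    cfg = SimulationConfig(
        n_cells=50, n_sites=40, n_marks=8, edit_fraction=0.7, detection_efficiency=1.0
    )
    tree, states, truth_cm, observed = simulate_experiment(cfg, 11)
    return cfg, tree, states, truth_cm, observed


@pytest.fixture
def balanced8():
    return LineageTree.from_newick("(((a,b),(c,d)),((e,f),(g,h)));")


def random_tree(rng: np.random.Generator, n_leaves: int, multifurcate: bool = False) -> LineageTree:
    """Random rooted topology by sequential leaf attachment."""
    import itertools
    import networkx as nx

    graph = nx.DiGraph()
    counter = itertools.count()
    leaves = [f"l{i}" for i in range(n_leaves)]
    root = f"i{next(counter)}"
    graph.add_edge(root, leaves[0])
    graph.add_edge(root, leaves[1])
    for leaf in leaves[2:]:
        edges = list(graph.edges)
        if multifurcate and rng.random() < 0.3:
            target = rng.choice([n for n in graph.nodes if graph.out_degree(n) > 0])
            graph.add_edge(target, leaf)
            continue
        u, v = edges[rng.integers(len(edges))]
        mid = f"i{next(counter)}"
        graph.remove_edge(u, v)
        graph.add_edge(u, mid)
        graph.add_edge(mid, v)
        graph.add_edge(mid, leaf)
    return LineageTree(graph, root)
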