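import networkx as nx
import numpy as np
import pytest

from subpathrx import PathwayGraph, SyntheticSpec, catalogue_subpathways, simulate_study


def make_pathway(pathway_id, edges, genes=None, name=""):
    """Small helper: pathway graph from an edge list, one gene per node by
    default (gene ID == node ID)."""
    g = nx.Graph()
    g.add_edges_from(edges)
    for n in g.nodes:
        g.nodes[n]["genes"] = frozenset(genes[n]) if genes else frozenset({n})
        g.nodes[n]["kind"] = "gene"
    return PathwayGraph(pathway_id=pathway_id, name=name or pathway_id, graph=g)


@pytest.fixture(scope="session")
def path_graph():
    """The path a-b-c-d-e."""
    return make_pathway("path:00001", [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")])


@pytest.fixture(scope="session")
def disjoint_catalogue():
    """Three disjoint triangles -> three disjoint sub-pathways, 9 genes."""
    pathways = [
        make_pathway(f"path:0000{i}",
                     [(f"{i}x", f"{i}y"), (f"{i}y", f"{i}z"), (f"{i}x", f"{i}z")])
        for i in (1, 2, 3)
    ]
    return catalogue_subpathways(pathways, k=3)


@pytest.fixture(scope="session")
def small_study():
    """A compact planted study reused by integration tests."""
    spec = SyntheticSpec(n_genes=400, n_pathways=8, n_molecules=8,
                         pathway_size_range=(4, 8), frac_de=0.06, seed=11)
    return simulate_study(spec, n_disease_subpathways=2, n_active_molecules=2)


def random_graph(rng: np.random.Generator, max_nodes: int = 12) -> nx.Graph:
    n = int(rng.integers(2, max_nodes + 1))
    g = nx.Graph()
    g.add_nodes_from(f"n{i}" for i in range(n))
    p = rng.uniform(0.1, 0.6)
    nodes = sorted(g.nodes)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(nodes[i], nodes[j])
    return g
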