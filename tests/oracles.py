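"""Independent brute-force oracles used to check the package's algorithms.

Everything here is deliberately naive — direct formula evaluation and
exhaustive enumeration — and shares no code with the implementation paths
it verifies.
"""

from fractions import Fraction
from itertools import combinations
from math import comb

import networkx as nx


def bh_stepup(p_values):
    """Direct evaluation of the Benjamini-Hochberg step-up formula."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [None] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, m * p_values[i] / rank)
        adjusted[i] = min(running_min, 1.0)
    return adjusted


def hypergeom_tail(N, K, n, x):
    """Exact upper tail P(X >= x) by term summation with rational arithmetic."""
    total = Fraction(0)
    for i in range(x, min(K, n) + 1):
        total += Fraction(comb(K, i) * comb(N - K, n - i), comb(N, n))
    return float(total)


def all_pairs_within(graph: nx.Graph, nodes, k: int, dist) -> bool:
    return all(dist.get(u, {}).get(v, float("inf")) <= k
               for u, v in combinations(nodes, 2))


def kclique_subsets(graph: nx.Graph, k: int) -> set[frozenset]:
    """All maximal node subsets with pairwise ambient distance <= k,
    by exhaustive enumeration (graphs of ~12 nodes at most)."""
    dist = dict(nx.all_pairs_shortest_path_length(graph))
    nodes = list(graph.nodes)
    feasible = []
    for r in range(1, len(nodes) + 1):
        for subset in combinations(nodes, r):
            if all_pairs_within(graph, subset, k, dist):
                feasible.append(frozenset(subset))
    maximal = {s for s in feasible
               if not any(s < t for t in feasible)}
    return maximal


def metabolic_edges(records) -> set[frozenset]:
    """Pairwise compound-intersection check over enzyme nodes."""
    compounds = {}
    for r in records:
        compounds.setdefault(r.enzyme_node_id, set()).update(
            r.substrate_compounds | r.product_compounds)
    return {
        frozenset((u, v))
        for u, v in combinations(sorted(compounds), 2)
        if compounds[u] & compounds[v]
    }
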