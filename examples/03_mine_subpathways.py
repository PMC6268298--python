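"""Mine k-clique sub-pathways from a pathway graph.

A sub-pathway is a maximal node set whose pairwise shortest-path distances
in the parent graph are at most k; smaller k demands tighter neighbourhoods.
"""

import networkx as nx

from subpathrx import PathwayGraph, mine_kcliques

# a path of six enzymes with one branch: a-b-c-d-e-f plus c-x
g = nx.Graph([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("e", "f"), ("c", "x")])
for n in g.nodes:
    g.nodes[n]["genes"] = frozenset({f"gene_{n}"})
pathway = PathwayGraph(pathway_id="path:00001", name="demo pathway", graph=g)

for k in (1, 2, 3):
    subpathways = mine_kcliques(pathway, k=k)
    print(f"k={k}: {len(subpathways)} sub-pathways")
    for sp in subpathways:
        print(f"  {sp.subpathway_id}: nodes {sorted(sp.node_ids)}")
# At k=1 sub-pathways are the maximal cliques of the graph itself; raising k
# merges nearby nodes until, at k=3, most of this small pathway fuses into a
# few overlapping neighbourhoods.
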