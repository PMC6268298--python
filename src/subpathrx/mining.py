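"""k-clique sub-pathway mining.

A sub-pathway of a pathway graph is a maximal set of nodes in which every
pair lies within shortest-path distance ``k`` of each other *in the parent
graph* (the social-network "k-clique", measured in the ambient graph, not the
induced sub-graph). Equivalently: the maximal cliques of the distance-``k``
closure of the pathway graph. With the default ``k = 3`` a sub-pathway is a
functionally tight neighbourhood — every member enzyme reachable from every
other in at most three steps.

The closure is built here by breadth-first search; maximal cliques of the
closure are enumerated with Bron-Kerbosch with pivoting
(:func:`networkx.find_cliques`). Both steps are exact; tests check the
combination against exhaustive subset enumeration on small graphs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

from .pathways import PathwayGraph

log = logging.getLogger(__name__)

__all__ = [
    "SubPathway",
    "SubPathwayCatalogue",
    "distance_closure",
    "mine_kcliques",
    "catalogue_subpathways",
    "write_gmt",
    "read_gmt",
]


@dataclass(frozen=True)
class SubPathway:
    """A mined sub-pathway: a maximal distance-k clique of one pathway."""

    subpathway_id: str  # "<pathway_id>_<n>", 1-based n
    pathway_id: str
    node_ids: frozenset
    gene_ids: frozenset
    k: int


@dataclass
class SubPathwayCatalogue:
    """The union of sub-pathways mined across a pathway collection."""

    subpathways: list[SubPathway] = field(default_factory=list)
    gene_universe: frozenset = frozenset()
    pathway_names: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.subpathways)

    def __iter__(self) -> Iterator[SubPathway]:
        return iter(self.subpathways)

    @property
    def ids(self) -> list[str]:
        return [sp.subpathway_id for sp in self.subpathways]

    def by_id(self, subpathway_id: str) -> SubPathway:
        for sp in self.subpathways:
            if sp.subpathway_id == subpathway_id:
                return sp
        raise KeyError(subpathway_id)

    def genes_of(self, subpathway_id: str) -> frozenset:
        return self.by_id(subpathway_id).gene_ids


def distance_closure(graph: nx.Graph, k: int) -> nx.Graph:
    """Graph on the same nodes with an edge wherever shortest-path
    distance <= k in ``graph`` (BFS, unweighted). Components are never joined
    (unreachable pairs have infinite distance)."""
    if int(k) < 1:
        raise ValueError(f"k must be a positive integer, got {k}")
    k = int(k)
    closure = nx.Graph()
    closure.add_nodes_from(graph.nodes(data=True))
    for u in graph.nodes:
        for v, d in nx.single_source_shortest_path_length(graph, u, cutoff=k).items():
            if v != u and d <= k:
                closure.add_edge(u, v)
    return closure


def _subpathway_sort_key(nodes: tuple) -> tuple:
    return (-len(nodes), min(str(n) for n in nodes), tuple(sorted(str(n) for n in nodes)))


def mine_kcliques(pathway: PathwayGraph, k: int = 3) -> list[SubPathway]:
    """All maximal distance-k cliques of one pathway graph.

    Singleton components come out as size-1 sub-pathways. Sub-pathway IDs are
    ``"<pathway_id>_<n>"`` with ``n`` assigned after sorting by (size
    descending, lexicographically smallest member node); the numbering is
    deterministic for a given graph.
    """
    g = pathway.graph
    if g.number_of_nodes() == 0:
        raise ValueError(f"pathway {pathway.pathway_id} has no nodes")
    closure = distance_closure(g, k)
    cliques = sorted((tuple(c) for c in nx.find_cliques(closure)),
                     key=_subpathway_sort_key)
    out = []
    for i, nodes in enumerate(cliques, start=1):
        genes: set = set()
        for n in nodes:
            genes |= g.nodes[n].get("genes", frozenset())
        out.append(SubPathway(
            subpathway_id=f"{pathway.pathway_id}_{i}",
            pathway_id=pathway.pathway_id,
            node_ids=frozenset(nodes),
            gene_ids=frozenset(genes),
            k=k,
        ))
    return out


def catalogue_subpathways(
    pathways: Iterable[PathwayGraph], k: int = 3, min_size: int = 1
) -> SubPathwayCatalogue:
    """Mine every pathway and merge the results into one catalogue.

    The catalogue's gene universe is the union of gene annotations over all
    included pathways (the background for enrichment). Pathways with no
    annotated gene at all are excluded with a warning. ``min_size`` drops
    sub-pathways with fewer member nodes (default keeps everything).
    """
    pathways = list(pathways)
    if not pathways:
        raise ValueError("at least one pathway is required")
    subpathways: list[SubPathway] = []
    universe: set = set()
    names: dict[str, str] = {}
    for pg in pathways:
        genes = pg.genes
        if not genes:
            log.warning("pathway %s has no annotated genes; excluded", pg.pathway_id)
            continue
        universe |= genes
        names[pg.pathway_id] = pg.name
        subpathways.extend(
            sp for sp in mine_kcliques(pg, k=k) if len(sp.node_ids) >= min_size
        )
    return SubPathwayCatalogue(
        subpathways=subpathways,
        gene_universe=frozenset(universe),
        pathway_names=names,
    )


# ----------------------------------------------------------------- formats

def write_gmt(catalogue: SubPathwayCatalogue, path: str | Path) -> None:
    """One line per sub-pathway: ID, parent-pathway description, gene IDs."""
    with open(path, "w") as fh:
        for sp in catalogue.subpathways:
            desc = catalogue.pathway_names.get(sp.pathway_id, sp.pathway_id)
            genes = "\t".join(sorted(sp.gene_ids))
            fh.write(f"{sp.subpathway_id}\t{desc}\t{genes}\n")


def read_gmt(path: str | Path) -> SubPathwayCatalogue:
    """Read a GMT catalogue back (node sets are not stored in GMT and come
    back empty; gene sets and the universe are reconstructed)."""
    subpathways: list[SubPathway] = []
    universe: set = set()
    names: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            spid, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            pathway_id = spid.rsplit("_", 1)[0]
            names.setdefault(pathway_id, desc)
            universe.update(genes)
            subpathways.append(SubPathway(
                subpathway_id=spid, pathway_id=pathway_id,
                node_ids=frozenset(), gene_ids=frozenset(genes), k=0,
            ))
    return SubPathwayCatalogue(subpathways=subpathways,
                               gene_universe=frozenset(universe),
                               pathway_names=names)


def write_catalogue_json(catalogue: SubPathwayCatalogue, path: str | Path) -> None:
    payload = {
        "gene_universe": sorted(catalogue.gene_universe),
        "pathway_names": dict(sorted(catalogue.pathway_names.items())),
        "subpathways": [
            {
                "subpathway_id": sp.subpathway_id,
                "pathway_id": sp.pathway_id,
                "nodes": sorted(str(n) for n in sp.node_ids),
                "genes": sorted(sp.gene_ids),
                "k": sp.k,
            }
            for sp in catalogue.subpathways
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))
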