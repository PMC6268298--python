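"""Pathway graphs: KGML parsing and undirected gene-graph construction.

A pathway is represented as an undirected simple graph whose nodes carry gene
annotations (possibly several genes per node, possibly none for compounds).
Metabolic pathways are rebuilt from reactions — two enzymes are linked when
their reactions share a compound — while signaling pathways use the relation
edges recorded in the KGML file, with compound-mediated relations collapsed
to a direct edge between the flanking gene nodes.

Both full KEGG KGML and the compact dialect written by
:mod:`subpathrx.synthetic` are read by the same parser; a plain node/edge TSV
pair is supported as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
from lxml import etree

log = logging.getLogger(__name__)

__all__ = [
    "PathwayGraph",
    "ReactionRecord",
    "parse_kgml",
    "build_metabolic_graph",
    "build_signaling_graph",
    "write_kgml",
    "write_graph_tsv",
    "read_graph_tsv",
]

#: KGML entry types that become gene-carrying nodes
_GENE_TYPES = {"gene", "enzyme", "ortholog"}


@dataclass
class PathwayGraph:
    """An undirected simple graph over gene-annotated pathway nodes.

    ``graph`` is a :class:`networkx.Graph`; each node has a ``genes``
    attribute (frozenset of gene IDs, possibly empty) and a ``kind``
    attribute ("gene" or "compound").
    """

    pathway_id: str
    name: str = ""
    graph: nx.Graph = field(default_factory=nx.Graph)
    provenance: str = ""

    def node_genes(self, node_id) -> frozenset:
        return self.graph.nodes[node_id].get("genes", frozenset())

    @property
    def genes(self) -> frozenset:
        """Union of gene annotations over all nodes."""
        out: set = set()
        for _, data in self.graph.nodes(data=True):
            out |= data.get("genes", frozenset())
        return frozenset(out)

    def gene_nodes(self) -> list:
        return [n for n, d in self.graph.nodes(data=True) if d.get("kind", "gene") != "compound"]


@dataclass(frozen=True)
class ReactionRecord:
    """One enzyme's participation in one reaction."""

    reaction_id: str
    enzyme_node_id: str
    substrate_compounds: frozenset
    product_compounds: frozenset

    @property
    def compounds(self) -> frozenset:
        return self.substrate_compounds | self.product_compounds


def _add_node(g: nx.Graph, node_id: str, genes: Iterable[str], kind: str) -> None:
    g.add_node(node_id, genes=frozenset(genes), kind=kind)


def parse_kgml(path: str | Path) -> tuple[PathwayGraph, list[ReactionRecord]]:
    """Parse a KGML (or compact-dialect) pathway file.

    Gene/enzyme/ortholog entries become nodes annotated with the gene IDs in
    their ``name`` attribute; compound entries become un-annotated mediator
    nodes; relation elements become candidate edges; reaction elements become
    :class:`ReactionRecord` rows (one per participating enzyme entry).
    Unknown entry types are skipped with a warning.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed XML in {path}: {exc}") from exc
    root = tree.getroot()
    pathway_id = root.get("name", path.stem)
    name = root.get("title", "")
    g = nx.Graph()
    reaction_of_entry: dict[str, str] = {}

    for entry in root.findall("entry"):
        etype = entry.get("type", "gene")
        eid = entry.get("id")
        if eid is None:
            continue
        names = (entry.get("name") or "").split()
        if etype in _GENE_TYPES:
            _add_node(g, eid, [n for n in names if n != "undefined"], "gene")
            if entry.get("reaction"):
                reaction_of_entry[eid] = entry.get("reaction")
        elif etype == "compound":
            _add_node(g, eid, [], "compound")
        else:
            log.warning("%s: skipping entry %s of unhandled type %r", path.name, eid, etype)

    for rel in root.findall("relation"):
        u, v = rel.get("entry1"), rel.get("entry2")
        if u is None or v is None or u == v:
            continue
        if g.has_node(u) and g.has_node(v):
            g.add_edge(u, v)

    reactions: list[ReactionRecord] = []
    for rxn in root.findall("reaction"):
        rid = rxn.get("name") or rxn.get("id") or f"rn:{len(reactions)}"
        subs = frozenset(s.get("name") or s.get("id") for s in rxn.findall("substrate"))
        prods = frozenset(s.get("name") or s.get("id") for s in rxn.findall("product"))
        enzymes = [e for e, r in reaction_of_entry.items() if r and rid in r.split()]
        if not enzymes and rxn.get("id") in g:
            enzymes = [rxn.get("id")]
        for e in enzymes:
            reactions.append(ReactionRecord(rid, e, subs, prods))

    if g.number_of_nodes() == 0:
        log.warning("%s: pathway %s contains no recognized entries", path.name, pathway_id)
    pg = PathwayGraph(pathway_id=pathway_id, name=name, graph=g,
                      provenance=f"{path.name}:kgml")
    return pg, reactions


def build_metabolic_graph(
    reactions: Iterable[ReactionRecord],
    *,
    pathway_id: str = "path:00000",
    name: str = "",
    node_genes: Mapping[str, Iterable[str]] | None = None,
) -> PathwayGraph:
    """Build the enzyme graph of a metabolic pathway from its reactions.

    Two enzymes are connected iff the compound sets of their reactions
    (substrates union products, direction ignored) intersect.
    """
    reactions = list(reactions)
    if not reactions:
        raise ValueError("at least one reaction is required")
    compounds: dict[str, set] = {}
    for r in reactions:
        compounds.setdefault(r.enzyme_node_id, set()).update(r.compounds)
    g = nx.Graph()
    for node, _ in compounds.items():
        genes = frozenset(node_genes.get(node, ())) if node_genes else frozenset({node})
        _add_node(g, node, genes, "gene")
    nodes = sorted(compounds)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            if compounds[u] & compounds[v]:
                g.add_edge(u, v)
    return PathwayGraph(pathway_id=pathway_id, name=name, graph=g,
                        provenance="reactions:metabolic")


def build_signaling_graph(parsed: PathwayGraph) -> PathwayGraph:
    """Symmetrized relation graph with compound mediators collapsed.

    Every relation edge is kept as an undirected edge. Each compound node is
    removed after connecting all pairs of its non-compound neighbours, so an
    a -> compound -> b chain becomes a direct a - b edge. Isolated gene nodes
    are retained.
    """
    g = nx.Graph()
    for n, d in parsed.graph.nodes(data=True):
        if d.get("kind", "gene") != "compound":
            _add_node(g, n, d.get("genes", frozenset()), "gene")
    for u, v in parsed.graph.edges():
        ku = parsed.graph.nodes[u].get("kind", "gene")
        kv = parsed.graph.nodes[v].get("kind", "gene")
        if ku != "compound" and kv != "compound":
            g.add_edge(u, v)
    for c, d in parsed.graph.nodes(data=True):
        if d.get("kind", "gene") == "compound":
            neigh = [n for n in parsed.graph.neighbors(c)
                     if parsed.graph.nodes[n].get("kind", "gene") != "compound"]
            for i, u in enumerate(neigh):
                for v in neigh[i + 1:]:
                    if u != v:
                        g.add_edge(u, v)
    g.remove_edges_from(nx.selfloop_edges(g))
    return PathwayGraph(pathway_id=parsed.pathway_id, name=parsed.name, graph=g,
                        provenance=parsed.provenance + ":signaling")


# ----------------------------------------------------------------- writers

def write_kgml(pg: PathwayGraph, path: str | Path) -> None:
    """Serialize a gene graph in the compact KGML dialect (re-readable by
    :func:`parse_kgml`)."""
    root = etree.Element("pathway", name=pg.pathway_id, title=pg.name)
    for n in sorted(pg.graph.nodes):
        d = pg.graph.nodes[n]
        kind = d.get("kind", "gene")
        etree.SubElement(
            root, "entry", id=str(n),
            name=" ".join(sorted(d.get("genes", frozenset()))),
            type="compound" if kind == "compound" else "gene",
        )
    for u, v in sorted(pg.graph.edges()):
        etree.SubElement(root, "relation", entry1=str(u), entry2=str(v), type="PPrel")
    etree.ElementTree(root).write(str(path), pretty_print=True,
                                  xml_declaration=True, encoding="UTF-8")


def write_graph_tsv(pg: PathwayGraph, nodes_path: str | Path, edges_path: str | Path) -> None:
    with open(nodes_path, "w") as fh:
        fh.write("node_id\tkind\tgenes\n")
        for n in sorted(pg.graph.nodes):
            d = pg.graph.nodes[n]
            fh.write(f"{n}\t{d.get('kind', 'gene')}\t"
                     f"{';'.join(sorted(d.get('genes', frozenset())))}\n")
    with open(edges_path, "w") as fh:
        fh.write("node1\tnode2\n")
        for u, v in sorted(tuple(sorted(e)) for e in pg.graph.edges()):
            fh.write(f"{u}\t{v}\n")


def read_graph_tsv(nodes_path: str | Path, edges_path: str | Path,
                   *, pathway_id: str = "path:00000", name: str = "") -> PathwayGraph:
    g = nx.Graph()
    with open(nodes_path) as fh:
        header = fh.readline()
        if not header.startswith("node_id"):
            raise ValueError("node TSV must start with a node_id header")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            node, kind = parts[0], parts[1] if len(parts) > 1 else "gene"
            genes = [x for x in (parts[2].split(";") if len(parts) > 2 and parts[2] else [])]
            _add_node(g, node, genes, kind)
    with open(edges_path) as fh:
        fh.readline()
        for line in fh:
            u, v = line.rstrip("\n").split("\t")[:2]
            if u != v:
                g.add_edge(u, v)
    return PathwayGraph(pathway_id=pathway_id, name=name, graph=g,
                        provenance=f"{nodes_path}:tsv")
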