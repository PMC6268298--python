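"""KGML parsing and metabolic/signaling graph construction."""

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from subpathrx import (ReactionRecord, build_metabolic_graph,
                       build_signaling_graph, parse_kgml, write_kgml)
from subpathrx.pathways import read_graph_tsv, write_graph_tsv

from conftest import make_pathway
from oracles import metabolic_edges


def write_xml(tmp_path, body, name="p.xml"):
    f = tmp_path / name
    f.write_text(body)
    return f


SIMPLE = """<?xml version="1.0"?>
<pathway name="path:00010" title="demo">
 <entry id="1" name="gA" type="gene"/>
 <entry id="2" name="gB gB2" type="gene"/>
 <entry id="3" name="gC" type="gene"/>
 <entry id="4" name="gD" type="gene"/>
 <entry id="5" name="gE" type="gene"/>
 <relation entry1="1" entry2="2" type="PPrel"/>
 <relation entry1="2" entry2="3" type="PPrel"/>
 <relation entry1="3" entry2="4" type="PPrel"/>
 <relation entry1="4" entry2="5" type="PPrel"/>
</pathway>
"""


class TestParseKgml:
    def test_nodes_edges_and_annotations(self, tmp_path):
        pg, reactions = parse_kgml(write_xml(tmp_path, SIMPLE))
        assert pg.pathway_id == "path:00010"
        assert pg.graph.number_of_nodes() == 5
        assert pg.graph.number_of_edges() == 4
        assert pg.node_genes("2") == frozenset({"gB", "gB2"})
        assert reactions == []

    def test_duplicate_relation_collapses_to_one_edge(self, tmp_path):
        body = SIMPLE.replace(
            '<relation entry1="1" entry2="2" type="PPrel"/>',
            '<relation entry1="1" entry2="2" type="PPrel"/>'
            '<relation entry1="2" entry2="1" type="PPrel"/>')
        pg, _ = parse_kgml(write_xml(tmp_path, body))
        assert pg.graph.number_of_edges() == 4

    def test_empty_pathway_warns_not_crashes(self, tmp_path, caplog):
        f = write_xml(tmp_path, '<?xml version="1.0"?><pathway name="path:1"/>')
        with caplog.at_level("WARNING"):
            pg, _ = parse_kgml(f)
        assert pg.graph.number_of_nodes() == 0
        assert "no recognized entries" in caplog.text

    def test_malformed_xml_raises_with_location(self, tmp_path):
        f = write_xml(tmp_path, "<pathway><entry</pathway>")
        with pytest.raises(ValueError, match="malformed XML"):
            parse_kgml(f)

    def test_unknown_entry_type_skipped_with_warning(self, tmp_path, caplog):
        body = SIMPLE.replace('<entry id="5" name="gE" type="gene"/>',
                              '<entry id="5" name="m1" type="map"/>')
        with caplog.at_level("WARNING"):
            pg, _ = parse_kgml(write_xml(tmp_path, body))
        assert "5" not in pg.graph
        assert "unhandled type" in caplog.text

    def test_reactions_are_recorded(self, tmp_path):
        body = """<?xml version="1.0"?>
        <pathway name="path:00020" title="rxn demo">
         <entry id="1" name="gA" type="enzyme" reaction="rn:R1"/>
         <entry id="2" name="gB" type="enzyme" reaction="rn:R2"/>
         <reaction name="rn:R1" type="irreversible">
          <substrate id="10" name="cpd:A"/><product id="11" name="cpd:B"/>
         </reaction>
         <reaction name="rn:R2" type="irreversible">
          <substrate id="11" name="cpd:B"/><product id="12" name="cpd:C"/>
         </reaction>
        </pathway>
        """
        _, reactions = parse_kgml(write_xml(tmp_path, body))
        assert {r.enzyme_node_id for r in reactions} == {"1", "2"}
        r1 = next(r for r in reactions if r.enzyme_node_id == "1")
        assert r1.substrate_compounds == frozenset({"cpd:A"})
        assert r1.product_compounds == frozenset({"cpd:B"})


class TestRoundTrips:
    def test_kgml_round_trip_is_isomorphic(self, tmp_path):
        pg = make_pathway("path:00042",
                          [("a", "b"), ("b", "c"), ("c", "d"), ("a", "d")])
        f = tmp_path / "rt.xml"
        write_kgml(pg, f)
        back, _ = parse_kgml(f)
        assert nx.is_isomorphic(pg.graph, back.graph)
        assert back.genes == pg.genes

    def test_tsv_round_trip(self, tmp_path):
        pg = make_pathway("path:00042", [("a", "b"), ("b", "c")])
        write_graph_tsv(pg, tmp_path / "n.tsv", tmp_path / "e.tsv")
        back = read_graph_tsv(tmp_path / "n.tsv", tmp_path / "e.tsv")
        assert set(back.graph.nodes) == set(pg.graph.nodes)
        assert set(map(frozenset, back.graph.edges)) == set(map(frozenset, pg.graph.edges))
        assert back.node_genes("a") == frozenset({"a"})


def rec(node, rid, subs, prods):
    return ReactionRecord(rid, node, frozenset(subs), frozenset(prods))


class TestMetabolicGraph:
    def test_shared_compound_makes_the_only_edge(self):
        pg = build_metabolic_graph([
            rec("e1", "r1", {"A"}, {"B"}),
            rec("e2", "r2", {"B"}, {"C"}),
            rec("e3", "r3", {"D"}, {"E"}),
        ])
        assert set(map(frozenset, pg.graph.edges)) == {frozenset({"e1", "e2"})}

    def test_no_shared_compound_no_edge(self):
        pg = build_metabolic_graph([
            rec("e1", "r1", {"A"}, {"B"}), rec("e2", "r2", {"C"}, {"D"})])
        assert pg.graph.number_of_edges() == 0

    def test_common_substrate_makes_triangle(self):
        pg = build_metabolic_graph([
            rec(e, f"r{e}", {"X"}, {e.upper()}) for e in ("e1", "e2", "e3")])
        assert pg.graph.number_of_edges() == 3

    def test_rejects_empty_reaction_list(self):
        with pytest.raises(ValueError):
            build_metabolic_graph([])

    def test_idempotent(self):
        records = [rec("e1", "r1", {"A"}, {"B"}), rec("e2", "r2", {"B"}, {"C"})]
        g1 = build_metabolic_graph(records)
        g2 = build_metabolic_graph(records)
        assert nx.utils.graphs_equal(g1.graph, g2.graph)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(
        st.tuples(st.integers(0, 14),
                  st.sets(st.integers(0, 9), max_size=3),
                  st.sets(st.integers(0, 9), max_size=3)),
        min_size=1, max_size=25))
    def test_matches_pairwise_oracle(self, raw):
        records = [rec(f"e{node}", f"r{i}", {f"c{c}" for c in subs},
                       {f"c{c}" for c in prods})
                   for i, (node, subs, prods) in enumerate(raw)]
        pg = build_metabolic_graph(records)
        assert set(map(frozenset, pg.graph.edges)) == metabolic_edges(records)


class TestSignalingGraph:
    def test_directed_relation_becomes_undirected_edge(self, tmp_path):
        pg, _ = parse_kgml(write_xml(tmp_path, SIMPLE))
        sig = build_signaling_graph(pg)
        assert sig.graph.has_edge("1", "2") and sig.graph.has_edge("2", "1")

    def test_compound_chain_collapses_to_direct_edge(self, tmp_path):
        body = """<?xml version="1.0"?>
        <pathway name="path:00030" title="pcrel">
         <entry id="1" name="gA" type="gene"/>
         <entry id="2" name="gB" type="gene"/>
         <entry id="9" name="cpd:X" type="compound"/>
         <relation entry1="1" entry2="9" type="PCrel"/>
         <relation entry1="9" entry2="2" type="PCrel"/>
        </pathway>
        """
        sig = build_signaling_graph(parse_kgml(write_xml(tmp_path, body))[0])
        assert sig.graph.has_edge("1", "2")
        assert "9" not in sig.graph

    def test_isolated_node_retained(self, tmp_path):
        body = SIMPLE.replace('<relation entry1="4" entry2="5" type="PPrel"/>', "")
        sig = build_signaling_graph(parse_kgml(write_xml(tmp_path, body))[0])
        assert "5" in sig.graph and sig.graph.degree("5") == 0
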