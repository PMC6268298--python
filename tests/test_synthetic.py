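"""The synthetic study generator: contracts, determinism, calibration."""

import dataclasses

import networkx as nx
import numpy as np
import pytest
from scipy import stats as sps

from subpathrx import (SyntheticSpec, catalogue_subpathways, generate_expression,
                       generate_molecule_instances, generate_pathways, parse_kgml,
                       select_degs, simulate_study, t_test_genes)


class TestSpecValidation:
    @pytest.mark.parametrize("field, value", [
        ("n_genes", 0), ("frac_de", 1.5), ("effect_size", 0.0),
        ("noise_sd", -1.0), ("pathway_size_range", (5, 2)),
        ("perturbed_subpathways_per_molecule", -1), ("pair_correlation", 1.0),
    ])
    def test_invalid_field_named_in_error(self, field, value):
        spec = dataclasses.replace(SyntheticSpec(), **{field: value})
        with pytest.raises(ValueError, match=field.split("_")[0]):
            spec.validate()

    def test_pathway_size_cannot_exceed_gene_universe(self):
        spec = SyntheticSpec(n_genes=8, pathway_size_range=(4, 10))
        with pytest.raises(ValueError, match="exceeds n_genes"):
            spec.validate()


class TestGenerateExpression:
    def test_de_count_follows_rounding_rule(self):
        spec = SyntheticSpec(n_genes=100, frac_de=0.2, seed=1)
        _, truth = generate_expression(spec)
        assert len(truth.de_genes) == 20

    def test_shape_and_groups(self):
        spec = SyntheticSpec(n_genes=50, n_case=4, n_control=6, seed=1)
        m, _ = generate_expression(spec)
        assert m.values.shape == (50, 10)
        assert len(m.samples_in_group("case")) == 4
        assert len(m.samples_in_group("control")) == 6

    def test_same_seed_bit_identical(self):
        spec = SyntheticSpec(n_genes=80, seed=9)
        a, _ = generate_expression(spec)
        b, _ = generate_expression(spec)
        assert a.values.equals(b.values)

    def test_different_seed_differs(self):
        a, _ = generate_expression(SyntheticSpec(n_genes=80, seed=1))
        b, _ = generate_expression(SyntheticSpec(n_genes=80, seed=2))
        assert not a.values.equals(b.values)

    def test_null_pvalues_uniform_over_replicates(self):
        """frac_de=0: two-sample t-test p-values are approximately uniform."""
        spec = SyntheticSpec(n_genes=300, frac_de=0.0, seed=0)
        ks = []
        for rep in range(50):
            m, truth = generate_expression(spec, rng=np.random.default_rng(500 + rep))
            assert truth.de_genes == frozenset()
            p = t_test_genes(m)["p_raw"].to_numpy()
            ks.append(sps.kstest(p, "uniform").statistic)
        assert np.mean(ks) < 0.06

    def test_null_deg_count_controlled(self):
        """With no signal the mean DEG count stays far below 10% of genes."""
        spec = SyntheticSpec(n_genes=200, frac_de=0.0, seed=0)
        counts = []
        for rep in range(50):
            m, _ = generate_expression(spec, rng=np.random.default_rng(900 + rep))
            counts.append(len(select_degs(t_test_genes(m), cutoff=0.1)))
        assert np.mean(counts) <= 0.1 * spec.n_genes

    def test_recall_monotone_in_effect_size(self):
        recalls = []
        for effect in (0.5, 1.0, 2.0):
            hits = []
            for rep in range(20):
                spec = SyntheticSpec(n_genes=300, frac_de=0.1, effect_size=effect)
                m, truth = generate_expression(
                    spec, rng=np.random.default_rng(1000 + rep))
                degs = select_degs(t_test_genes(m), cutoff=0.1)
                hits.append(len(degs & truth.de_genes) / len(truth.de_genes))
            recalls.append(np.mean(hits))
        assert recalls[0] <= recalls[1] <= recalls[2]


class TestGeneratePathways:
    def test_counts_sizes_connectivity(self):
        spec = SyntheticSpec(n_genes=100, n_pathways=5, pathway_size_range=(4, 10))
        pathways = generate_pathways(spec)
        assert len(pathways) == 5
        for pg in pathways:
            assert 4 <= pg.graph.number_of_nodes() <= 10
            assert nx.is_connected(pg.graph)
            assert all(pg.node_genes(n) for n in pg.graph.nodes)

    def test_exact_size_range(self):
        spec = SyntheticSpec(n_genes=100, n_pathways=4, pathway_size_range=(3, 3))
        assert all(pg.graph.number_of_nodes() == 3
                   for pg in generate_pathways(spec))

    def test_kgml_round_trip_isomorphic(self, tmp_path):
        from subpathrx import write_kgml
        spec = SyntheticSpec(n_genes=60, n_pathways=2, pathway_size_range=(5, 8))
        for pg in generate_pathways(spec):
            f = tmp_path / f"{pg.pathway_id.replace(':', '_')}.xml"
            write_kgml(pg, f)
            back, _ = parse_kgml(f)
            assert nx.is_isomorphic(pg.graph, back.graph)
            assert back.genes == pg.genes

    def test_multi_gene_nodes(self):
        spec = SyntheticSpec(n_genes=200, n_pathways=2, pathway_size_range=(4, 6))
        for pg in generate_pathways(spec, genes_per_node=3):
            assert all(len(pg.node_genes(n)) == 3 for n in pg.graph.nodes)


class TestGenerateMoleculeInstances:
    def catalogue(self, spec):
        return catalogue_subpathways(generate_pathways(spec), k=3)

    def test_no_perturbation_means_no_shift(self):
        spec = SyntheticSpec(n_genes=100, n_pathways=3, n_molecules=3,
                             instances_per_molecule=4,
                             perturbed_subpathways_per_molecule=0, seed=2)
        cat = self.catalogue(spec)
        from subpathrx import GroundTruth
        truth = GroundTruth()
        table = generate_molecule_instances(spec, cat, truth)
        assert all(not v for v in truth.perturbed_map.values())
        # treatment-minus-control differences should be centred at zero
        for m in table.molecule_ids:
            inst = table.instances_of(m)
            d = (table.expression.values[list(inst["treatment_sample"])].to_numpy()
                 - table.expression.values[list(inst["control_sample"])].to_numpy())
            assert abs(d.mean()) < 0.1

    def test_requesting_too_many_subpathways_rejected(self):
        spec = SyntheticSpec(n_genes=100, n_pathways=1, pathway_size_range=(3, 3),
                             perturbed_subpathways_per_molecule=50)
        cat = self.catalogue(spec)
        from subpathrx import GroundTruth
        with pytest.raises(ValueError, match="catalogue has only"):
            generate_molecule_instances(spec, cat, GroundTruth())

    def test_fixed_seed_identical_table(self):
        spec = SyntheticSpec(n_genes=100, n_pathways=3, n_molecules=2,
                             instances_per_molecule=3, seed=5)
        cat = self.catalogue(spec)
        from subpathrx import GroundTruth
        a = generate_molecule_instances(spec, cat, GroundTruth())
        b = generate_molecule_instances(spec, cat, GroundTruth())
        assert a.expression.values.equals(b.expression.values)
        assert a.records.equals(b.records)


class TestSimulateStudy:
    def test_ground_truth_is_consistent(self, small_study):
        cat_ids = set(small_study.catalogue.ids)
        assert small_study.truth.disease_subpathways <= cat_ids
        for sps_ in small_study.truth.perturbed_map.values():
            assert sps_ <= small_study.truth.disease_subpathways
        planted_genes = set().union(
            *(small_study.catalogue.genes_of(sp)
              for sp in small_study.truth.disease_subpathways))
        assert planted_genes <= small_study.truth.de_genes

    def test_study_write_round_trip(self, small_study, tmp_path):
        from subpathrx import ExpressionMatrix, InstanceTable
        small_study.write(tmp_path)
        m = ExpressionMatrix.from_tsv(tmp_path / "expression.tsv",
                                      tmp_path / "groups.tsv")
        assert m.values.shape == small_study.expression.values.shape
        t = InstanceTable.from_tsv(tmp_path / "instances.tsv",
                                   tmp_path / "instance_expression.tsv")
        assert t.molecule_ids == small_study.instances.molecule_ids
        assert len(list((tmp_path / "pathways").glob("*.xml"))) == \
            len(small_study.pathways)
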