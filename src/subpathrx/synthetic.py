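"""Synthetic study generator with known planted structure.

Emulates, at desk scale, the three data sources of a sub-pathway
repositioning study: a blood-microarray case/control cohort (two balanced
groups, thousands of genes on a log-intensity scale, a planted fraction
differentially expressed), a collection of pathway graphs, and a
connectivity-map style instance table of treatment/control pairs per small
molecule with planted sub-pathway perturbations. Every planted element is
recorded in a :class:`GroundTruth` so downstream recovery can be measured
exactly.

Noise is Gaussian with equal variance in both groups (matching the t-test
model downstream); pathway graphs are random connected graphs (spanning tree
plus extra edges) so the miner sees varied clique structure rather than any
one realistic topology.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .drugs import InstanceTable, INSTANCE_COLUMNS
from .expression import ExpressionMatrix
from .mining import SubPathwayCatalogue, catalogue_subpathways
from .pathways import PathwayGraph, write_kgml

log = logging.getLogger(__name__)

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "SyntheticStudy",
    "generate_expression",
    "generate_pathways",
    "generate_molecule_instances",
    "simulate_study",
]

#: baseline log2-intensity distribution for a gene's mean (typical of
#: normalized bead-array data)
_BASELINE_MEAN, _BASELINE_SD = 7.0, 1.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic study.

    Defaults describe the standard desk-scale scenario: a 16 vs 16 cohort
    over 1,000 genes with 5% differentially expressed at a two-standard-
    deviation shift, 20 pathways of 5-12 nodes, and 20 molecules profiled
    with 10 treatment/control instances each.
    """

    n_genes: int = 1000
    n_case: int = 16
    n_control: int = 16
    frac_de: float = 0.05
    effect_size: float = 2.0      # standardized mean shift, in units of noise_sd
    noise_sd: float = 1.0
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (5, 12)
    n_molecules: int = 20
    instances_per_molecule: int = 10
    perturbed_subpathways_per_molecule: int = 2
    pair_correlation: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_case", "n_control", "n_pathways",
                     "n_molecules", "instances_per_molecule"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError(f"frac_de must lie in [0, 1], got {self.frac_de}")
        if self.effect_size <= 0:
            raise ValueError(f"effect_size must be > 0, got {self.effect_size}")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")
        if not 0.0 <= self.pair_correlation < 1.0:
            raise ValueError(f"pair_correlation must lie in [0, 1), got "
                             f"{self.pair_correlation}")
        if self.perturbed_subpathways_per_molecule < 0:
            raise ValueError(
                "perturbed_subpathways_per_molecule must be >= 0, got "
                f"{self.perturbed_subpathways_per_molecule}")
        lo, hi = self.pathway_size_range
        if not (1 <= lo <= hi):
            raise ValueError(f"pathway_size_range must satisfy 1 <= low <= high, "
                             f"got {self.pathway_size_range}")
        if hi > self.n_genes:
            raise ValueError(f"pathway_size_range high ({hi}) exceeds n_genes "
                             f"({self.n_genes})")

    @property
    def gene_ids(self) -> list[str]:
        return [f"g{i:04d}" for i in range(1, self.n_genes + 1)]

    @property
    def n_de(self) -> int:
        return int(round(self.frac_de * self.n_genes))


@dataclass
class GroundTruth:
    """What was planted: the DE gene set, the disease sub-pathways whose
    genes carry the disease signal, and each molecule's perturbed
    sub-pathways."""

    de_genes: frozenset = frozenset()
    disease_subpathways: frozenset = frozenset()
    perturbed_map: dict[str, frozenset] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "de_genes": sorted(self.de_genes),
            "disease_subpathways": sorted(self.disease_subpathways),
            "perturbed_map": {m: sorted(s) for m, s in sorted(self.perturbed_map.items())},
        }, indent=1))


@dataclass
class SyntheticStudy:
    """A complete generated study: all inputs plus ground truth."""

    spec: SyntheticSpec
    expression: ExpressionMatrix
    pathways: list[PathwayGraph]
    catalogue: SubPathwayCatalogue
    instances: InstanceTable
    truth: GroundTruth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.expression.to_tsv(outdir / "expression.tsv", outdir / "groups.tsv")
        pdir = outdir / "pathways"
        pdir.mkdir(exist_ok=True)
        for pg in self.pathways:
            write_kgml(pg, pdir / f"{pg.pathway_id.replace(':', '_')}.xml")
        self.instances.to_tsv(outdir / "instances.tsv",
                              outdir / "instance_expression.tsv")
        self.truth.to_json(outdir / "ground_truth.json")


# ------------------------------------------------------------- expression

def generate_expression(
    spec: SyntheticSpec,
    *,
    de_genes: Iterable[str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Case/control matrix with ``round(frac_de * n_genes)`` planted DE genes.

    DE genes get a group-mean difference of ``effect_size * noise_sd`` with a
    random sign; all other genes share the same mean in both groups. Passing
    ``de_genes`` overrides the random choice (used when planting the signal
    inside chosen sub-pathways).
    """
    spec.validate()
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    genes = spec.gene_ids
    if de_genes is None:
        de = sorted(map(str, rng.choice(genes, size=spec.n_de, replace=False))) if spec.n_de else []
    else:
        de = sorted(set(de_genes))
        unknown = set(de) - set(genes)
        if unknown:
            raise ValueError(f"de_genes outside the gene universe: {sorted(unknown)[:5]}")
    samples = ([f"case_{i:02d}" for i in range(1, spec.n_case + 1)]
               + [f"ctrl_{i:02d}" for i in range(1, spec.n_control + 1)])
    groups = {s: ("case" if s.startswith("case") else "control") for s in samples}

    baseline = rng.normal(_BASELINE_MEAN, _BASELINE_SD, size=spec.n_genes)
    values = baseline[:, None] + rng.normal(0.0, spec.noise_sd,
                                            size=(spec.n_genes, len(samples)))
    gene_index = {g: i for i, g in enumerate(genes)}
    signs = rng.choice([-1.0, 1.0], size=len(de))
    for g, s in zip(de, signs):
        values[gene_index[g], : spec.n_case] += s * spec.effect_size * spec.noise_sd
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                            columns=samples),
        groups=groups,
    )
    return matrix, GroundTruth(de_genes=frozenset(de))


# --------------------------------------------------------------- pathways

def generate_pathways(
    spec: SyntheticSpec,
    *,
    rng: np.random.Generator | None = None,
    genes_per_node: int = 1,
) -> list[PathwayGraph]:
    """Random connected pathway graphs with gene-annotated nodes.

    Each graph is a uniform random recursive tree plus ``size // 2`` extra
    random edges, sized uniformly within ``pathway_size_range``. Nodes carry
    ``genes_per_node`` genes drawn without replacement within a pathway
    (different pathways may share genes, as real pathways do).
    """
    spec.validate()
    if genes_per_node < 1:
        raise ValueError("genes_per_node must be >= 1")
    lo, hi = spec.pathway_size_range
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    genes = spec.gene_ids
    out: list[PathwayGraph] = []
    for p in range(1, spec.n_pathways + 1):
        size = int(rng.integers(lo, hi + 1))
        need = size * genes_per_node
        if need > spec.n_genes:
            raise ValueError(f"pathway of {size} nodes x {genes_per_node} genes "
                             f"needs {need} genes but the universe has {spec.n_genes}")
        assigned = rng.choice(genes, size=need, replace=False)
        g = nx.Graph()
        node_ids = [f"n{j}" for j in range(1, size + 1)]
        for j, node in enumerate(node_ids):
            g.add_node(node,
                       genes=frozenset(assigned[j * genes_per_node:(j + 1) * genes_per_node]),
                       kind="gene")
        for j in range(1, size):  # random recursive tree => connected
            g.add_edge(node_ids[j], node_ids[int(rng.integers(0, j))])
        for _ in range(size // 2):
            u, v = rng.integers(0, size, size=2)
            if u != v:
                g.add_edge(node_ids[int(u)], node_ids[int(v)])
        out.append(PathwayGraph(pathway_id=f"path:9{p:04d}",
                                name=f"synthetic pathway {p}",
                                graph=g, provenance="synthetic"))
    return out


# -------------------------------------------------------------- molecules

def generate_molecule_instances(
    spec: SyntheticSpec,
    catalogue: SubPathwayCatalogue,
    truth: GroundTruth,
    *,
    perturbed_map: Mapping[str, Iterable[str]] | None = None,
    rng: np.random.Generator | None = None,
) -> InstanceTable:
    """Treatment/control instance profiles with planted sub-pathway shifts.

    Each molecule gets ``instances_per_molecule`` paired columns. Genes in a
    molecule's planted sub-pathways are shifted by
    ``effect_size * noise_sd`` (per-gene random sign, constant across that
    molecule's instances) in the treatment columns only. By default every
    molecule perturbs ``perturbed_subpathways_per_molecule`` sub-pathways
    drawn from the catalogue; ``perturbed_map`` overrides the assignment
    (molecule IDs absent from the map perturb nothing). The planted map is
    recorded in ``truth.perturbed_map``.

    The two columns of an instance come from the same culture/batch, so a
    fraction ``pair_correlation`` of each column's noise variance is shared
    within the pair (every column still has marginal standard deviation
    ``noise_sd``); the paired differences the downstream t-test works on
    have standard deviation ``sqrt(2 * (1 - pair_correlation)) * noise_sd``.
    """
    spec.validate()
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    n_per = spec.perturbed_subpathways_per_molecule
    if n_per > 0 and len(catalogue) == 0:
        raise ValueError("non-empty catalogue required to plant perturbations")
    if n_per > len(catalogue) and perturbed_map is None:
        raise ValueError(f"cannot plant {n_per} sub-pathways per molecule: "
                         f"catalogue has only {len(catalogue)}")
    molecules = [f"mol{m:03d}" for m in range(1, spec.n_molecules + 1)]
    if perturbed_map is None:
        ids = catalogue.ids
        perturbed = {m: frozenset(map(str, rng.choice(ids, size=n_per, replace=False)))
                     for m in molecules}
    else:
        unknown = {sp for s in perturbed_map.values() for sp in s} - set(catalogue.ids)
        if unknown:
            raise ValueError(f"perturbed_map references unknown sub-pathways: "
                             f"{sorted(unknown)[:5]}")
        perturbed = {m: frozenset(perturbed_map.get(m, ())) for m in molecules}

    genes = spec.gene_ids
    gene_index = {g: i for i, g in enumerate(genes)}
    baseline = rng.normal(_BASELINE_MEAN, _BASELINE_SD, size=spec.n_genes)
    records, columns, blocks = [], [], []
    for m in molecules:
        shift = np.zeros(spec.n_genes)
        target_genes = sorted(set().union(
            *(catalogue.genes_of(sp) for sp in sorted(perturbed[m]))) if perturbed[m] else set())
        signs = rng.choice([-1.0, 1.0], size=len(target_genes))
        for g, s in zip(target_genes, signs):
            shift[gene_index[g]] = s * spec.effect_size * spec.noise_sd
        shared_sd = spec.noise_sd * np.sqrt(spec.pair_correlation)
        own_sd = spec.noise_sd * np.sqrt(1.0 - spec.pair_correlation)
        for i in range(1, spec.instances_per_molecule + 1):
            t_col, c_col = f"{m}_i{i:02d}_t", f"{m}_i{i:02d}_c"
            records.append((m, f"{m}_i{i:02d}", t_col, c_col))
            shared = rng.normal(0.0, shared_sd, size=spec.n_genes)
            own = rng.normal(0.0, own_sd, size=(spec.n_genes, 2))
            blocks.append(baseline + shared + own[:, 0] + shift)   # treatment
            blocks.append(baseline + shared + own[:, 1])           # control
            columns.extend([t_col, c_col])
    expr = ExpressionMatrix(
        values=pd.DataFrame(np.column_stack(blocks),
                            index=pd.Index(genes, name="gene_id"), columns=columns))
    truth.perturbed_map = dict(perturbed)
    return InstanceTable(
        records=pd.DataFrame(records, columns=INSTANCE_COLUMNS), expression=expr)


# ------------------------------------------------------------ whole study

def simulate_study(
    spec: SyntheticSpec,
    *,
    n_disease_subpathways: int = 3,
    n_active_molecules: int = 3,
    k: int = 3,
    min_subpathway_genes: int = 3,
) -> SyntheticStudy:
    """Generate a complete study with coupled disease and drug signal.

    ``n_disease_subpathways`` sub-pathways (with at least
    ``min_subpathway_genes`` genes) are chosen as the disease-perturbed
    regions: their genes are planted as differentially expressed in the
    cohort, topped up with random genes until ``round(frac_de * n_genes)``
    DE genes exist. ``n_active_molecules`` molecules then perturb
    ``perturbed_subpathways_per_molecule`` of those same disease
    sub-pathways; the remaining molecules perturb nothing. All randomness
    derives from ``spec.seed``.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rng_p, rng_e, rng_m, rng_pick = (np.random.default_rng(c) for c in ss.spawn(4))

    pathways = generate_pathways(spec, rng=rng_p)
    catalogue = catalogue_subpathways(pathways, k=k)
    eligible = [sp.subpathway_id for sp in catalogue
                if len(sp.gene_ids) >= min_subpathway_genes]
    if len(eligible) < n_disease_subpathways:
        raise ValueError(f"only {len(eligible)} sub-pathways with >= "
                         f"{min_subpathway_genes} genes; cannot plant "
                         f"{n_disease_subpathways}")
    disease_sps = sorted(map(str, rng_pick.choice(eligible, size=n_disease_subpathways,
                                                replace=False)))
    planted_genes = set().union(*(catalogue.genes_of(sp) for sp in disease_sps))
    de = set(planted_genes)
    extra = spec.n_de - len(de)
    if extra > 0:
        pool = sorted(set(spec.gene_ids) - de)
        de |= set(map(str, rng_pick.choice(pool, size=extra, replace=False)))

    expression, truth = generate_expression(spec, de_genes=de, rng=rng_e)
    truth.disease_subpathways = frozenset(disease_sps)

    if spec.perturbed_subpathways_per_molecule > n_disease_subpathways:
        raise ValueError("perturbed_subpathways_per_molecule exceeds the number "
                         "of planted disease sub-pathways")
    molecules = [f"mol{m:03d}" for m in range(1, spec.n_molecules + 1)]
    active = sorted(map(str, rng_pick.choice(molecules, size=min(n_active_molecules, len(molecules)),
                                           replace=False)))
    perturbed_map = {
        m: frozenset(map(str, rng_pick.choice(
            disease_sps, size=spec.perturbed_subpathways_per_molecule,
            replace=False)))
        for m in active
    }
    instances = generate_molecule_instances(spec, catalogue, truth,
                                            perturbed_map=perturbed_map, rng=rng_m)
    return SyntheticStudy(spec=spec, expression=expression, pathways=pathways,
                          catalogue=catalogue, instances=instances, truth=truth)
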