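"""End-to-end orchestration of the two-arm analysis.

Disease arm: expression -> DEGs -> sub-pathway catalogue -> enrichment at
raw p < 0.01. Drug arm: instance table -> per-molecule DEGs -> enrichment at
FDR < 0.005. Scoring: hypergeometric overlap of the two enriched sets over
the mined sub-pathway universe, ranked candidates, bipartite network.

Every threshold is a named config field defaulting to the published value;
a config hash plus the seed fully determine all outputs, and CSVs are
written in a fixed sort order so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .deg import collapse_probes, select_degs, t_test_genes
from .drugs import (InstanceTable, MoleculeSignature, build_molecule_signatures,
                    write_molecule_enrichment_csv, write_signatures_json)
from .enrichment import enrich_signature
from .expression import ExpressionMatrix, read_probe_map
from .mining import (SubPathwayCatalogue, catalogue_subpathways,
                     write_catalogue_json, write_gmt)
from .pathways import PathwayGraph, build_metabolic_graph, build_signaling_graph, parse_kgml
from .scoring import (CandidateMolecule, annotate_drugbank, build_network,
                      score_candidates, write_candidates_csv, write_graphml, write_sif)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "DiseaseArmResult", "PipelineResult",
           "disease_arm", "full_pipeline", "run_disease_arm", "run_full",
           "load_pathways"]


@dataclass
class PipelineConfig:
    """All inputs and tunables of one pipeline run."""

    expression: str | None = None
    groups: str | None = None
    pathways_dir: str | None = None
    instances: str | None = None
    instance_expression: str | None = None
    probe_map: str | None = None
    annotations: str | None = None
    outdir: str = "results"

    k: int = 3                            # sub-pathway distance parameter
    deg_cutoff: float = 0.1               # disease DEGs, BH-adjusted p
    deg_on_adjusted: bool = True
    equal_var: bool = True                # pooled (classical) t-test
    disease_enrich_cutoff: float = 0.01   # raw hypergeometric p
    drug_enrich_cutoff: float = 0.005     # BH-adjusted p (FDR)
    molecule_deg_cutoff: float = 0.1      # per-molecule BH-adjusted p
    single_instance_threshold: float = 1.0
    overlap_method: str = "hypergeom"     # or "fisher"
    overlap_universe: str = "mined"       # or "drug_enriched"
    min_subpathway_size: int = 1
    seed: int = 0

    def validate(self) -> None:
        if int(self.k) < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        for name in ("deg_cutoff", "disease_enrich_cutoff", "drug_enrich_cutoff",
                     "molecule_deg_cutoff"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.overlap_universe not in {"mined", "drug_enriched"}:
            raise ValueError("overlap_universe must be 'mined' or 'drug_enriched'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class DiseaseArmResult:
    deg_stats: pd.DataFrame
    degs: frozenset
    catalogue: SubPathwayCatalogue
    enrichment: pd.DataFrame
    enriched_subpathways: frozenset


@dataclass
class PipelineResult:
    disease: DiseaseArmResult
    signatures: list[MoleculeSignature]
    candidates: list[CandidateMolecule]
    manifest: dict = field(default_factory=dict)

    @property
    def notice(self) -> str | None:
        return self.manifest.get("notice")


def load_pathways(pathways_dir: str | Path) -> list[PathwayGraph]:
    """Parse every ``*.xml`` pathway file in a directory.

    Files carrying reactions are rebuilt as metabolic graphs (common-compound
    edges); the rest use their relation edges with compound mediators
    collapsed.
    """
    files = sorted(Path(pathways_dir).glob("*.xml"))
    if not files:
        raise ValueError(f"no pathway XML files in {pathways_dir}")
    out = []
    for f in files:
        parsed, reactions = parse_kgml(f)
        if reactions:
            node_genes = {n: parsed.node_genes(n) for n in parsed.graph.nodes}
            out.append(build_metabolic_graph(
                reactions, pathway_id=parsed.pathway_id, name=parsed.name,
                node_genes=node_genes))
        else:
            out.append(build_signaling_graph(parsed))
    return out


# ---------------------------------------------------------------- in-memory

def disease_arm(expression: ExpressionMatrix, catalogue: SubPathwayCatalogue,
                config: PipelineConfig | None = None) -> DiseaseArmResult:
    """DEG scoring and disease sub-pathway enrichment, in memory."""
    cfg = config or PipelineConfig()
    cfg.validate()
    stats = t_test_genes(expression, equal_var=cfg.equal_var)
    degs = frozenset(select_degs(stats, cutoff=cfg.deg_cutoff,
                                 use_adjusted=cfg.deg_on_adjusted))
    enr = enrich_signature(degs, catalogue, threshold_mode="p",
                           cutoff=cfg.disease_enrich_cutoff)
    enriched = frozenset(enr["subpathway_id"]) if not enr.empty else frozenset()
    log.info("disease arm: %d genes, %d DEGs, %d/%d sub-pathways enriched",
             len(stats), len(degs), len(enriched), len(catalogue))
    return DiseaseArmResult(deg_stats=stats, degs=degs, catalogue=catalogue,
                            enrichment=enr, enriched_subpathways=enriched)


def full_pipeline(
    expression: ExpressionMatrix,
    pathways: list[PathwayGraph],
    instances: InstanceTable,
    config: PipelineConfig | None = None,
    annotations: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run both arms, score candidates, and assemble the run manifest."""
    cfg = config or PipelineConfig()
    cfg.validate()
    catalogue = catalogue_subpathways(pathways, k=cfg.k,
                                      min_size=cfg.min_subpathway_size)
    disease = disease_arm(expression, catalogue, cfg)
    signatures = build_molecule_signatures(
        instances, catalogue, fdr_cutoff=cfg.drug_enrich_cutoff,
        deg_alpha=cfg.molecule_deg_cutoff,
        single_instance_threshold=cfg.single_instance_threshold)

    molecule_sets = {s.molecule_id: s.enriched_subpathways for s in signatures
                     if s.enriched_subpathways}
    if cfg.overlap_universe == "mined":
        universe_size = len(catalogue)
    else:
        drug_union = set().union(*molecule_sets.values()) if molecule_sets else set()
        universe_size = len(drug_union | disease.enriched_subpathways)

    notice = None
    if not disease.enriched_subpathways:
        notice = "no disease-enriched sub-pathways; candidate table is empty"
        log.warning(notice)
        candidates: list[CandidateMolecule] = []
    else:
        candidates = score_candidates(disease.enriched_subpathways, molecule_sets,
                                      universe_size, method=cfg.overlap_method)
    if annotations is not None:
        candidates = annotate_drugbank(candidates, annotations)

    manifest = {
        "package_version": __version__,
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "counts": {
            "genes": int(len(disease.deg_stats)),
            "degs": int(len(disease.degs)),
            "pathways": int(len(pathways)),
            "subpathways": int(len(catalogue)),
            "disease_enriched_subpathways": int(len(disease.enriched_subpathways)),
            "molecules": int(len(signatures)),
            "molecules_with_degs": int(sum(1 for s in signatures if s.deg_genes)),
            "molecules_with_enrichment": int(len(molecule_sets)),
            "candidates": int(len(candidates)),
        },
    }
    if notice:
        manifest["notice"] = notice
    return PipelineResult(disease=disease, signatures=signatures,
                          candidates=candidates, manifest=manifest)


# --------------------------------------------------------------- file-based

def _load_expression(cfg: PipelineConfig) -> ExpressionMatrix:
    matrix = ExpressionMatrix.from_tsv(cfg.expression, cfg.groups)
    if cfg.probe_map:
        matrix = collapse_probes(matrix, read_probe_map(cfg.probe_map))
    return matrix


def _write_disease_outputs(result: DiseaseArmResult, outdir: Path) -> None:
    result.deg_stats.sort_index().to_csv(outdir / "gene_stats.csv")
    (outdir / "deg_list.txt").write_text("\n".join(sorted(result.degs)) + "\n")
    write_gmt(result.catalogue, outdir / "subpathways.gmt")
    write_catalogue_json(result.catalogue, outdir / "subpathways.json")
    result.enrichment.to_csv(outdir / "disease_enrichment.csv", index=False)


def run_disease_arm(config: PipelineConfig) -> DiseaseArmResult:
    """File-based disease arm: read inputs, write all intermediates."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        expression = _load_expression(config)
    except Exception as exc:
        raise RuntimeError(f"stage 'load expression' failed: {exc}") from exc
    try:
        pathways = load_pathways(config.pathways_dir)
        catalogue = catalogue_subpathways(pathways, k=config.k,
                                          min_size=config.min_subpathway_size)
    except Exception as exc:
        raise RuntimeError(f"stage 'mine sub-pathways' failed: {exc}") from exc
    try:
        result = disease_arm(expression, catalogue, config)
    except Exception as exc:
        raise RuntimeError(f"stage 'disease enrichment' failed: {exc}") from exc
    _write_disease_outputs(result, outdir)
    return result


def run_full(config: PipelineConfig) -> PipelineResult:
    """File-based full pipeline: both arms, scoring, network, manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expression = _load_expression(config)
    pathways = load_pathways(config.pathways_dir)
    instances = InstanceTable.from_tsv(config.instances, config.instance_expression)
    annotations = None
    if config.annotations:
        annotations = pd.read_csv(config.annotations, sep="\t", keep_default_na=False)
    result = full_pipeline(expression, pathways, instances, config, annotations)

    _write_disease_outputs(result.disease, outdir)
    write_signatures_json(result.signatures, outdir / "molecule_signatures.json")
    write_molecule_enrichment_csv(result.signatures, outdir / "molecule_enrichment.csv")
    write_candidates_csv(result.candidates, outdir / "candidates.csv")
    if result.candidates:
        network = build_network(result.candidates, result.disease.catalogue)
        write_sif(network, outdir / "network.sif")
        write_graphml(network, outdir / "network.graphml")
    (outdir / "run_manifest.json").write_text(json.dumps(result.manifest, indent=1))
    return result
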