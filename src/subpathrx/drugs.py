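"""Per-molecule perturbation signatures from treatment/control instances.

A connectivity-map style experiment records, for each small molecule, one or
more *instances*: a treated expression profile paired with its vehicle
control. The molecule's signature is the set of genes whose paired
treatment-minus-control differences are consistently non-zero — a one-sample
t-test across instances with BH adjustment (p_adj < 0.1 by default), or a
plain absolute-difference threshold when only one instance exists and a
t-test is undefined. Each molecule's signature is then enriched against the
sub-pathway catalogue at a strict FDR (default 0.005).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .enrichment import enrich_signature
from .expression import ExpressionMatrix
from .mining import SubPathwayCatalogue
from .stats import adjust_bh

log = logging.getLogger(__name__)

__all__ = ["InstanceTable", "MoleculeSignature", "molecule_degs",
           "build_molecule_signatures"]

_P_FLOOR = float(np.nextafter(0.0, 1.0))

INSTANCE_COLUMNS = ["molecule_id", "instance_id", "treatment_sample", "control_sample"]


@dataclass
class InstanceTable:
    """Treatment/control instance records plus the expression matrix that
    holds every referenced sample column."""

    records: pd.DataFrame  # columns INSTANCE_COLUMNS
    expression: ExpressionMatrix

    def __post_init__(self) -> None:
        missing_cols = set(INSTANCE_COLUMNS) - set(self.records.columns)
        if missing_cols:
            raise ValueError(f"instance table missing columns: {sorted(missing_cols)}")
        referenced = set(self.records["treatment_sample"]) | set(self.records["control_sample"])
        absent = referenced - set(self.expression.sample_ids)
        if absent:
            raise ValueError(f"instances reference unknown samples: {sorted(absent)[:5]}")

    @property
    def molecule_ids(self) -> list[str]:
        return sorted(self.records["molecule_id"].unique())

    def instances_of(self, molecule_id: str) -> pd.DataFrame:
        sel = self.records[self.records["molecule_id"] == molecule_id]
        if sel.empty:
            raise KeyError(f"unknown molecule: {molecule_id}")
        return sel

    def to_tsv(self, records_path: str | Path, expression_path: str | Path) -> None:
        self.records[INSTANCE_COLUMNS].to_csv(records_path, sep="\t", index=False)
        self.expression.to_tsv(expression_path)

    @classmethod
    def from_tsv(cls, records_path: str | Path, expression_path: str | Path) -> "InstanceTable":
        records = pd.read_csv(records_path, sep="\t", dtype=str)
        return cls(records=records, expression=ExpressionMatrix.from_tsv(expression_path))


@dataclass
class MoleculeSignature:
    molecule_id: str
    deg_genes: frozenset
    n_instances: int
    enriched_subpathways: frozenset
    enrichment: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)


def molecule_degs(
    table: InstanceTable,
    molecule_id: str,
    *,
    alpha: float = 0.1,
    single_instance_threshold: float = 1.0,
) -> frozenset:
    """Genes differentially expressed under one molecule's treatment.

    With >=2 instances: per-gene one-sample t-test on the paired
    treatment - control differences against zero, BH over all genes, keep
    p_adj < ``alpha``. With a single instance the t-test is undefined and a
    gene is kept when its absolute log-difference exceeds
    ``single_instance_threshold``.
    """
    inst = table.instances_of(molecule_id)
    expr = table.expression.values
    diffs = (expr[list(inst["treatment_sample"])].to_numpy(float)
             - expr[list(inst["control_sample"])].to_numpy(float))
    if diffs.shape[1] == 1:
        keep = np.abs(diffs[:, 0]) > single_instance_threshold
        return frozenset(np.asarray(expr.index)[keep])
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = sps.ttest_1samp(diffs, 0.0, axis=1)
    # constant differences: p = 1 if they are zero, floor if shifted
    const = sd == 0
    p = np.where(const & (mean == 0), 1.0, p)
    p = np.where(const & (mean != 0), _P_FLOOR, p)
    p_adj = adjust_bh(p)
    return frozenset(np.asarray(expr.index)[p_adj < alpha])


def build_molecule_signatures(
    table: InstanceTable,
    catalogue: SubPathwayCatalogue,
    *,
    fdr_cutoff: float = 0.005,
    deg_alpha: float = 0.1,
    single_instance_threshold: float = 1.0,
) -> list[MoleculeSignature]:
    """DEG signature and sub-pathway enrichment for every molecule.

    Molecules are processed independently (removing one molecule's instances
    never changes another's signature) in sorted molecule-ID order. A
    molecule without DEGs yields an empty enrichment.
    """
    if len(catalogue) == 0:
        raise ValueError("empty sub-pathway catalogue")
    out: list[MoleculeSignature] = []
    for mol in table.molecule_ids:
        degs = molecule_degs(table, mol, alpha=deg_alpha,
                             single_instance_threshold=single_instance_threshold)
        if degs:
            enr = enrich_signature(degs, catalogue, threshold_mode="fdr",
                                   cutoff=fdr_cutoff)
        else:
            enr = enrich_signature(frozenset(), catalogue, threshold_mode="fdr",
                                   cutoff=fdr_cutoff)
        out.append(MoleculeSignature(
            molecule_id=mol,
            deg_genes=degs,
            n_instances=int(len(table.instances_of(mol))),
            enriched_subpathways=frozenset(enr["subpathway_id"]) if not enr.empty else frozenset(),
            enrichment=enr,
        ))
    return out


def write_signatures_json(signatures: list[MoleculeSignature], path: str | Path) -> None:
    payload = [
        {
            "molecule_id": s.molecule_id,
            "n_instances": s.n_instances,
            "deg_genes": sorted(s.deg_genes),
            "enriched_subpathways": sorted(s.enriched_subpathways),
        }
        for s in signatures
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def write_molecule_enrichment_csv(signatures: list[MoleculeSignature], path: str | Path) -> None:
    rows = []
    for s in signatures:
        for _, r in s.enrichment.iterrows():
            rows.append((s.molecule_id, r["subpathway_id"], r["p"], r["p_adj"]))
    pd.DataFrame(rows, columns=["molecule_id", "subpathway_id", "p", "p_adj"]) \
        .to_csv(path, index=False)
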