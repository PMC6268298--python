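"""Candidate ranking and the molecule--sub-pathway bipartite network.

A molecule becomes a repositioning candidate when the sub-pathways enriched
in its perturbation signature overlap the sub-pathways enriched in the
disease signature. The overlap's significance is the hypergeometric upper
tail over the mined sub-pathway universe: drawing the molecule's n enriched
sub-pathways from the N mined ones, of which K are disease-enriched, and
seeing x or more in common. Candidates are ranked by ascending overlap
p-value; no p cutoff is applied (any molecule with x >= 1 is reported).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd
from scipy.stats import fisher_exact

from .mining import SubPathwayCatalogue
from .stats import hypergeom_test

log = logging.getLogger(__name__)

__all__ = [
    "CandidateMolecule",
    "score_overlap",
    "score_candidates",
    "rank_candidates",
    "build_network",
    "annotate_drugbank",
    "write_candidates_csv",
    "read_candidates_csv",
    "write_sif",
]

CANDIDATE_COLUMNS = ["drugbank_id", "molecule", "p_value", "n_overlap", "type"]


@dataclass(frozen=True)
class CandidateMolecule:
    molecule_id: str
    overlap_subpathways: frozenset
    n_overlap: int
    p_overlap: float
    drugbank_id: str = ""
    type: str = "unknown"


def score_overlap(
    molecule_id: str,
    disease_set: Iterable[str],
    molecule_set: Iterable[str],
    universe_size: int,
    *,
    method: str = "hypergeom",
) -> CandidateMolecule | None:
    """Score one molecule's sub-pathway overlap with the disease set.

    ``universe_size`` is the number of mined sub-pathways the two sets were
    drawn from. Returns ``None`` for molecules with empty overlap (they are
    not candidates). ``method`` may be "hypergeom" (upper tail, default) or
    "fisher" (two-sided Fisher exact on the 2x2 table).
    """
    disease = frozenset(disease_set)
    mol = frozenset(molecule_set)
    N = int(universe_size)
    if N < len(disease | mol):
        raise ValueError(
            f"universe_size={N} smaller than |disease ∪ molecule|={len(disease | mol)}"
        )
    overlap = disease & mol
    x = len(overlap)
    if x == 0:
        return None
    K, n = len(disease), len(mol)
    if method == "hypergeom":
        p = hypergeom_test(N, K, n, x)
    elif method == "fisher":
        table = [[x, n - x], [K - x, N - K - (n - x)]]
        p = float(fisher_exact(table, alternative="two-sided")[1])
    else:
        raise ValueError("method must be 'hypergeom' or 'fisher'")
    return CandidateMolecule(molecule_id=molecule_id, overlap_subpathways=overlap,
                             n_overlap=x, p_overlap=p)


def score_candidates(
    disease_set: Iterable[str],
    molecule_sets: dict[str, Iterable[str]],
    universe_size: int,
    *,
    method: str = "hypergeom",
) -> list["CandidateMolecule"]:
    """Score every molecule against the disease set and rank the candidates."""
    out = []
    for mol_id in sorted(molecule_sets):
        cand = score_overlap(mol_id, disease_set, molecule_sets[mol_id],
                             universe_size, method=method)
        if cand is not None:
            out.append(cand)
    return rank_candidates(out)


def rank_candidates(candidates: Sequence[CandidateMolecule]) -> list[CandidateMolecule]:
    """Ascending overlap p; ties broken by larger overlap, then molecule ID."""
    return sorted(candidates,
                  key=lambda c: (c.p_overlap, -c.n_overlap, c.molecule_id))


def build_network(
    candidates: Sequence[CandidateMolecule],
    catalogue: SubPathwayCatalogue | None = None,
) -> nx.Graph:
    """Bipartite molecule--sub-pathway graph over the candidates' overlaps.

    Molecule nodes get ``kind="molecule"``; sub-pathway nodes get
    ``kind="subpathway"`` and a ``pathway_group`` attribute (the parent
    pathway ID) so visualisation tools can colour them by entire pathway.
    Every sub-pathway node has at least one incident edge by construction.
    """
    if not candidates:
        raise ValueError("at least one candidate is required")
    g = nx.Graph()
    for c in candidates:
        g.add_node(c.molecule_id, kind="molecule", p_overlap=float(c.p_overlap))
        for sp in sorted(c.overlap_subpathways):
            if sp not in g:
                group = sp.rsplit("_", 1)[0]
                if catalogue is not None:
                    try:
                        group = catalogue.by_id(sp).pathway_id
                    except KeyError:
                        pass
                g.add_node(sp, kind="subpathway", pathway_group=group)
            g.add_edge(c.molecule_id, sp)
    return g


def annotate_drugbank(
    candidates: Sequence[CandidateMolecule],
    annotations: pd.DataFrame,
) -> list[CandidateMolecule]:
    """Left-join DrugBank IDs and approval type by case-insensitive name.

    ``annotations`` needs columns molecule, drugbank_id, type. Molecules
    absent from the table keep a blank ID and type "unknown". Duplicate
    names in the table (case-insensitive) are rejected.
    """
    if annotations.empty:
        return [replace(c, drugbank_id="", type="unknown") for c in candidates]
    needed = {"molecule", "drugbank_id", "type"}
    if not needed <= set(annotations.columns):
        raise ValueError(f"annotation table must have columns {sorted(needed)}")
    keys = annotations["molecule"].str.lower()
    if keys.duplicated().any():
        dupes = sorted(keys[keys.duplicated()].unique())
        raise ValueError(f"duplicate molecule names in annotation table: {dupes}")
    lookup = {
        k: (str(r["drugbank_id"]) if pd.notna(r["drugbank_id"]) else "",
            str(r["type"]) if pd.notna(r["type"]) and str(r["type"]) else "unknown")
        for k, (_, r) in zip(keys, annotations.iterrows())
    }
    out = []
    for c in candidates:
        dbid, typ = lookup.get(c.molecule_id.lower(), ("", "unknown"))
        out.append(replace(c, drugbank_id=dbid, type=typ))
    return out


# ----------------------------------------------------------------- formats

def write_candidates_csv(candidates: Sequence[CandidateMolecule], path: str | Path) -> None:
    """Candidate table CSV: drugbank_id, molecule, p_value, n_overlap, type."""
    pd.DataFrame(
        [(c.drugbank_id, c.molecule_id, c.p_overlap, c.n_overlap, c.type)
         for c in candidates],
        columns=CANDIDATE_COLUMNS,
    ).to_csv(path, index=False)


def read_candidates_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"drugbank_id": str, "molecule": str, "type": str},
                     keep_default_na=False)
    df["p_value"] = df["p_value"].astype(float)
    df["n_overlap"] = df["n_overlap"].astype(int)
    return df


def write_sif(network: nx.Graph, path: str | Path) -> None:
    """SIF export: `molecule perturbs subpathway`, one edge per line."""
    with open(path, "w") as fh:
        for u, v in sorted(network.edges()):
            if network.nodes[u].get("kind") == "molecule":
                fh.write(f"{u}\tperturbs\t{v}\n")
            else:
                fh.write(f"{v}\tperturbs\t{u}\n")


def write_graphml(network: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(network, str(path))
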