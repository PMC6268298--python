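"""Packaged reference results of the ankylosing spondylitis case study.

The published AS analysis (GSE25101 blood transcriptomes, 16 patients vs 16
controls, against the June-2011 KEGG snapshot and CMap build 02) reported 35
enriched sub-pathways across 18 entire metabolic pathways and 15 candidate
small molecules. Those two result tables ship with the package as TSV
transcriptions: they anchor the output formats, serve as parsing/round-trip
fixtures, and give a concrete worked example without any external download.
The counts are reference points, not quantities this package recomputes —
they depend on database snapshots that are not bundled.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_reference_subpathways",
    "load_reference_candidates",
    "reference_summary",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("subpathrx.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", keep_default_na=False)


def load_reference_subpathways() -> pd.DataFrame:
    """Disease-enriched sub-pathways of the AS case study (35 rows).

    Columns: pathway_id, pathway_name, subpathway_id, p_value.
    """
    df = _read("as_enriched_subpathways.tsv")
    df["p_value"] = df["p_value"].astype(float)
    return df


def load_reference_candidates() -> pd.DataFrame:
    """Candidate small molecules of the AS case study (15 rows).

    Columns: drugbank_id, molecule, p_value, n_overlap, type (blank type
    means no DrugBank annotation was reported).
    """
    df = _read("as_candidate_molecules.tsv")
    df["p_value"] = df["p_value"].astype(float)
    df["n_overlap"] = df["n_overlap"].astype(int)
    return df


def reference_summary() -> dict:
    """Headline counts of the reference tables, computed from the data."""
    sub = load_reference_subpathways()
    cand = load_reference_candidates()
    overlaps = cand.sort_values("n_overlap", ascending=False)["n_overlap"]
    return {
        "n_enriched_subpathways": int(len(sub)),
        "n_entire_pathways": int(sub["pathway_id"].nunique()),
        "n_candidate_molecules": int(len(cand)),
        "max_overlap": int(overlaps.iloc[0]),
        "second_overlap": int(overlaps.iloc[1]),
        "top_molecule": str(cand.loc[cand["n_overlap"].idxmax(), "molecule"]),
    }
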