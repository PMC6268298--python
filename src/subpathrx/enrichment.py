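"""Hypergeometric enrichment of a gene signature against the sub-pathway
catalogue.

The same machinery serves both arms of the analysis: the disease arm filters
on the raw hypergeometric p (default cutoff 0.01), the drug arm on the
BH-adjusted p (FDR, default cutoff 0.005). The background universe is the
set of genes annotated to the pathway collection (not the whole array),
mirroring the convention of pathway-structure enrichment tools; signatures
are intersected with the universe before testing.
"""

from __future__ import annotations

import logging
from typing import Iterable

import pandas as pd

from .mining import SubPathwayCatalogue
from .stats import adjust_bh, hypergeom_test

log = logging.getLogger(__name__)

__all__ = ["enrich_signature", "RESULT_COLUMNS"]

RESULT_COLUMNS = ["subpathway_id", "pathway_id", "pathway_name",
                  "N", "K", "n", "x", "p", "p_adj"]


def enrich_signature(
    signature: Iterable[str],
    catalogue: SubPathwayCatalogue,
    threshold_mode: str = "p",
    cutoff: float | None = 0.01,
    *,
    universe: Iterable[str] | None = None,
    adjust_over_all: bool = False,
) -> pd.DataFrame:
    """Test every sub-pathway for over-representation of ``signature``.

    Parameters
    ----------
    signature
        Gene IDs of interest (e.g. the disease or molecule DEG set).
    catalogue
        Mined sub-pathway catalogue supplying gene sets and the universe.
    threshold_mode
        "p" filters on the raw p-value, "fdr" on the BH-adjusted one.
    cutoff
        Significance cutoff; ``None`` returns all tested sub-pathways.
    universe
        Override the background (default: the catalogue's gene universe,
        i.e. all genes annotated to any pathway).
    adjust_over_all
        When True, BH counts every catalogue sub-pathway as a test; by
        default only sub-pathways overlapping the signature (x >= 1) enter
        the family, since zero-overlap sets have p = 1 by construction.

    Returns
    -------
    DataFrame with columns subpathway_id, pathway_id, pathway_name, N, K, n,
    x, p, p_adj, sorted by (p, subpathway_id); only x >= 1 rows are reported.
    """
    if threshold_mode not in {"p", "fdr"}:
        raise ValueError("threshold_mode must be 'p' or 'fdr'")
    if len(catalogue) == 0:
        raise ValueError("empty sub-pathway catalogue")
    uni = frozenset(universe) if universe is not None else catalogue.gene_universe
    signature = frozenset(signature)
    sig = signature & uni
    if not sig and signature:
        log.warning("signature has no genes in the %d-gene universe", len(uni))
    N, n = len(uni), len(sig)

    rows = []
    for sp in catalogue.subpathways:
        gene_set = sp.gene_ids & uni
        K = len(gene_set)
        x = len(sig & gene_set)
        if x >= 1:
            rows.append((sp.subpathway_id, sp.pathway_id,
                         catalogue.pathway_names.get(sp.pathway_id, sp.pathway_id),
                         N, K, n, x, hypergeom_test(N, K, n, x)))
        elif adjust_over_all and K >= 1:
            rows.append((sp.subpathway_id, sp.pathway_id,
                         catalogue.pathway_names.get(sp.pathway_id, sp.pathway_id),
                         N, K, n, 0, 1.0))
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS[:-1])
    if df.empty:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    df["p_adj"] = adjust_bh(df["p"].to_numpy())
    if adjust_over_all:
        df = df[df["x"] >= 1]  # untested sets only widened the BH family
    if cutoff is not None:
        col = "p" if threshold_mode == "p" else "p_adj"
        df = df[df[col] < cutoff]
    return (df.sort_values(["p", "subpathway_id"], kind="mergesort")
              .reset_index(drop=True))
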