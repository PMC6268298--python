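"""Differential expression between case and control groups.

The disease signature is the set of genes whose two-sample t-test survives a
Benjamini-Hochberg adjusted p-value cutoff (default 0.1). Probe-level arrays
are first collapsed to one row per gene by averaging the probes mapped to it.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .expression import ExpressionMatrix
from .stats import adjust_bh

log = logging.getLogger(__name__)

__all__ = ["collapse_probes", "t_test_genes", "select_degs"]

#: smallest representable positive double, used when group means differ but
#: the pooled variance is exactly zero (t is formally infinite)
_P_FLOOR = float(np.nextafter(0.0, 1.0))


def collapse_probes(matrix: ExpressionMatrix, probe_map: Mapping[str, str]) -> ExpressionMatrix:
    """Collapse a probe-level matrix to gene level by per-sample averaging.

    Each gene's value in a sample is the arithmetic mean of that sample's
    values over all probes mapped to the gene. Probes absent from
    ``probe_map`` are dropped with a warning.
    """
    if matrix.values.empty:
        raise ValueError("cannot collapse an empty expression matrix")
    probes = matrix.values.index
    unmapped = [p for p in probes if p not in probe_map]
    if unmapped:
        log.warning("dropping %d unmapped probes (e.g. %s)", len(unmapped), unmapped[:5])
    mapped = matrix.values.loc[[p for p in probes if p in probe_map]]
    if mapped.empty:
        raise ValueError("no probes remain after applying the probe map")
    genes = pd.Index([probe_map[p] for p in mapped.index], name="gene_id")
    collapsed = mapped.groupby(genes, sort=True).mean()
    return ExpressionMatrix(values=collapsed, groups=dict(matrix.groups))


def t_test_genes(matrix: ExpressionMatrix, equal_var: bool = True) -> pd.DataFrame:
    """Per-gene two-sided two-sample t-test, case vs control.

    Parameters
    ----------
    matrix
        Gene-level matrix whose samples are labelled "case"/"control";
        both groups need at least two samples.
    equal_var
        Pooled-variance (classical) t-test when True; Welch when False.

    Returns
    -------
    DataFrame indexed by gene_id with columns ``t``, ``p_raw``, ``p_adj``
    (BH over all tested genes) and ``log_fc`` (mean case - mean control).

    Degenerate genes are resolved by convention: zero variance in both groups
    with equal means gives t = 0, p = 1; with unequal means the p-value is
    floored at the smallest positive double and a warning is logged.
    """
    case = matrix.samples_in_group("case")
    ctrl = matrix.samples_in_group("control")
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError(
            f"both groups need >=2 samples (case={len(case)}, control={len(ctrl)})"
        )
    a = matrix.values[case].to_numpy(float)
    b = matrix.values[ctrl].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = sps.ttest_ind(a, b, axis=1, equal_var=equal_var)
    log_fc = a.mean(axis=1) - b.mean(axis=1)

    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    equal_means = degenerate & np.isclose(log_fc, 0.0)
    shifted = degenerate & ~equal_means
    t = np.where(equal_means, 0.0, t)
    p = np.where(equal_means, 1.0, p)
    if shifted.any():
        log.warning(
            "%d genes have zero variance in both groups but unequal means; "
            "p floored at %.3g", int(shifted.sum()), _P_FLOOR,
        )
        t = np.where(shifted, np.sign(log_fc) * np.inf, t)
        p = np.where(shifted, _P_FLOOR, p)

    return pd.DataFrame(
        {"t": t, "p_raw": p, "p_adj": adjust_bh(p), "log_fc": log_fc},
        index=pd.Index(matrix.gene_ids, name="gene_id"),
    )


def select_degs(stats: pd.DataFrame, cutoff: float = 0.1, use_adjusted: bool = True) -> set[str]:
    """Genes passing the significance cutoff (on BH-adjusted p by default)."""
    if stats.empty:
        raise ValueError("empty statistics table")
    col = "p_adj" if use_adjusted else "p_raw"
    return set(stats.index[stats[col] < cutoff])
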