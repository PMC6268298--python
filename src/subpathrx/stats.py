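"""Shared statistical primitives: BH step-up adjustment and the hypergeometric tail.

Both the disease arm and the drug arm funnel through these two functions, so
enrichment p-values and overlap p-values are guaranteed to agree on identical
counts.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["adjust_bh", "hypergeom_test"]


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    Equivalent to sorting ascending, taking ``min_{j>=i}(m * p_(j) / j)`` capped
    at 1, and undoing the sort.

    Parameters
    ----------
    p_values : array-like of float in [0, 1]

    Returns
    -------
    numpy.ndarray of the same length.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return np.empty(0, dtype=float)
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_test(N: int, K: int, n: int, x: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= x).

    Models drawing ``n`` genes without replacement from a universe of ``N``
    genes of which ``K`` are annotated to the set of interest, and observing
    ``x`` or more annotated genes. Computed in log space by scipy's survival
    function, so it is stable for extreme tails.

    Raises
    ------
    ValueError
        If the counts are inconsistent (x > min(K, n), K > N, n > N, or any
        count negative).
    """
    N, K, n, x = int(N), int(K), int(n), int(x)
    if min(N, K, n, x) < 0:
        raise ValueError("counts must be non-negative")
    if K > N or n > N:
        raise ValueError(f"K={K} and n={n} must not exceed N={N}")
    if x > min(K, n):
        raise ValueError(f"overlap x={x} exceeds min(K={K}, n={n})")
    if x == 0:
        return 1.0
    p = float(hypergeom.sf(x - 1, N, K, n))
    # guard against tiny negative round-off and keep p in (0, 1]
    return min(max(p, np.nextafter(0.0, 1.0)), 1.0)
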