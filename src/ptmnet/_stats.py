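"""Shared statistical primitives: one-sided Fisher enrichment and BH-FDR.

Every 2x2 contingency test in the package funnels through
:func:`fisher_enrichment_p` so that a single, well-tested tail computation
backs co-existence, cross-protein interaction, GO and disease tests alike.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "fisher_enrichment_p",
    "fisher_table_p",
    "bh_adjust",
]


def fisher_enrichment_p(k: int, big_n: int, big_k: int, n: int) -> float:
    """One-sided (enrichment) Fisher exact p-value from hypergeometric counts.

    Parameters
    ----------
    k
        Observed overlap (successes in the sample).
    big_n
        Universe size.
    big_k
        Number of "marked" elements in the universe.
    n
        Sample size drawn from the universe.

    Returns
    -------
    float
        ``P(X >= k)`` for ``X ~ Hypergeometric(big_n, big_k, n)``; identical
        to ``scipy.stats.fisher_exact(table, alternative="greater")[1]``.
    """
    if not (0 <= big_k <= big_n and 0 <= n <= big_n):
        raise ValueError(f"inconsistent hypergeometric counts: N={big_n}, K={big_k}, n={n}")
    if k < 0:
        raise ValueError("overlap count must be non-negative")
    return float(stats.hypergeom.sf(k - 1, big_n, big_k, n))


def fisher_table_p(table, alternative: str = "greater") -> float:
    """Fisher exact p for an explicit 2x2 table ``[[a, b], [c, d]]``."""
    a, b = table[0]
    c, d = table[1]
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative")
    if alternative == "greater":
        # tail of the hypergeometric: universe a+b+c+d, marked a+b, drawn a+c
        return fisher_enrichment_p(a, a + b + c + d, a + b, a + c)
    return float(stats.fisher_exact([[a, b], [c, d]], alternative=alternative)[1])


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries (untested members of the family) are passed through as NaN
    and do not count toward the family size.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    finite = ~np.isnan(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if finite.sum():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out
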