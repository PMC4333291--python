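"""Group comparisons of network properties between PTM carriers and non-carriers.

For each PTM type, the proteins carrying it are compared against the
remaining proteins of the interaction network on degree, clustering
coefficient and closeness centrality with a two-sided Mann-Whitney test.
Effect sizes are reported as log2 fold differences of the group medians
(mean-based when a median is zero, flagged). P-values are BH-FDR adjusted
within one family per network property, pooling all species, PTM types and
network sources, and a comparison is only attempted when the carrier group
holds at least 30 proteins with a valid property value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust

PROPERTIES = ("degree", "clustering", "closeness")


@dataclass
class ComparisonResult:
    """One PTM-type x property x species x source comparison."""

    species: int
    source_label: str
    ptm_type: str
    property: str
    n_ptm: int
    n_ref: int
    median_ptm: float = math.nan
    median_ref: float = math.nan
    mean_ptm: float = math.nan
    mean_ref: float = math.nan
    log2_fold: float = math.nan
    fold_basis: str = "median"  # "mean" when a median is 0
    p_raw: float = math.nan
    p_fdr: float = math.nan
    direction: str = "none"
    mean_median_discordant: bool = False
    tested: bool = True

    @property
    def log2_fold_median(self) -> float:
        return self.log2_fold if self.fold_basis == "median" else math.nan


@dataclass
class CorrelationResult:
    species: int
    ptm_type: str
    property: str
    r: float
    p: float
    n: int


def _log2_ratio(a: float, b: float) -> float:
    if a <= 0 or b <= 0:
        return math.nan
    return math.log2(a / b)


def compare_type(
    props: pd.DataFrame,
    ptm_proteins: set,
    species: int = 0,
    source_label: str = "synthetic",
    ptm_type: str = "ptm",
    min_n: int = 30,
    properties: Sequence[str] = PROPERTIES,
) -> list[ComparisonResult]:
    """Mann-Whitney comparison of carriers vs. the network complement.

    The carrier set is intersected with the property-table universe; the
    reference set is the complement within that universe. Rows with an
    undefined property value (NaN clustering for degree < 2) are excluded
    from both groups for that property. No test is performed (result
    flagged untested) when the intersected carrier group has fewer than
    ``min_n`` members with a valid value.
    """
    universe = set(props.index)
    carriers = ptm_proteins & universe
    reference = universe - carriers
    if not reference:
        raise ValueError("reference set is empty: the PTM set covers the whole universe")
    out: list[ComparisonResult] = []
    in_ptm = props.index.isin(carriers)
    for prop in properties:
        vals = props[prop].to_numpy(dtype=float)
        valid = ~np.isnan(vals)
        x = vals[valid & in_ptm]
        y = vals[valid & ~in_ptm]
        res = ComparisonResult(
            species=species,
            source_label=source_label,
            ptm_type=ptm_type,
            property=prop,
            n_ptm=len(x),
            n_ref=len(y),
        )
        if len(x) < min_n or len(y) == 0:
            res.tested = False
            out.append(res)
            continue
        res.median_ptm, res.median_ref = float(np.median(x)), float(np.median(y))
        res.mean_ptm, res.mean_ref = float(x.mean()), float(y.mean())
        fold_med = _log2_ratio(res.median_ptm, res.median_ref)
        fold_mean = _log2_ratio(res.mean_ptm, res.mean_ref)
        if res.median_ptm == 0 or res.median_ref == 0:
            # a zero median makes the ratio degenerate: report the mean-based
            # fold instead and flag the cell
            res.log2_fold, res.fold_basis = fold_mean, "mean"
            res.mean_median_discordant = True
        else:
            res.log2_fold = fold_med
            # flag cells whose mean-based direction contradicts the median-based one
            if not math.isnan(fold_mean) and fold_mean * fold_med < 0:
                res.mean_median_discordant = True
        # normal approximation with tie correction; exact is infeasible at n>30
        res.p_raw = float(
            stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        )
        if res.median_ptm != res.median_ref:
            res.direction = "higher" if res.median_ptm > res.median_ref else "lower"
        elif res.mean_ptm != res.mean_ref:
            # tied medians (common on discrete degree distributions) carry no
            # direction; fall back to the means and flag the discordance
            res.direction = "higher" if res.mean_ptm > res.mean_ref else "lower"
            res.mean_median_discordant = True
        out.append(res)
    return out


def fdr_adjust(pvals: Sequence[float]) -> np.ndarray:
    """BH step-up adjustment for one family of raw p-values."""
    return bh_adjust(pvals)


def adjust_results(
    results: Iterable[ComparisonResult], family: str = "property"
) -> list[ComparisonResult]:
    """Fill ``p_fdr`` in place, one BH family per network property.

    ``family="global"`` pools every comparison into a single family
    (sensitivity-analysis mode). Untested results keep NaN.
    """
    results = list(results)
    if family == "property":
        keys = {r.property for r in results}
        groups = [[r for r in results if r.property == k] for k in sorted(keys)]
    elif family == "global":
        groups = [results]
    else:
        raise ValueError(f"unknown FDR family {family!r}")
    for group in groups:
        tested = [r for r in group if r.tested and not math.isnan(r.p_raw)]
        if not tested:
            continue
        adj = bh_adjust([r.p_raw for r in tested])
        for r, a in zip(tested, adj):
            r.p_fdr = float(a)
    return results


def results_frame(results: Iterable[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def fold_change_matrix(
    results: Iterable[ComparisonResult], property: str = "degree"
) -> pd.DataFrame:
    """Species x source rows by PTM-type columns of log2 fold differences.

    Cells of untested comparisons are NaN. A companion ``marks`` frame with
    significance asterisks (``*`` for FDR < 0.05, ``**`` for < 0.01, ``~``
    appended where mean- and median-based directions disagree) is attached
    as ``df.attrs["marks"]``.
    """
    rows = [r for r in results if r.property == property]
    if not rows:
        return pd.DataFrame()
    idx = sorted({(r.species, r.source_label) for r in rows})
    cols = sorted({r.ptm_type for r in rows})
    index = pd.MultiIndex.from_tuples(idx, names=["species", "source"])
    mat = pd.DataFrame(np.nan, index=index, columns=cols)
    marks = pd.DataFrame("", index=index, columns=cols)
    for r in rows:
        if not r.tested:
            continue
        mat.loc[(r.species, r.source_label), r.ptm_type] = r.log2_fold
        m = ""
        if not math.isnan(r.p_fdr):
            if r.p_fdr < 0.01:
                m = "**"
            elif r.p_fdr < 0.05:
                m = "*"
        if r.mean_median_discordant:
            m += "~"
        marks.loc[(r.species, r.source_label), r.ptm_type] = m
    mat.attrs["marks"] = marks
    return mat


def ptm_count_correlation(
    props: pd.DataFrame,
    site_counts: Mapping[str, int],
    species: int = 0,
    ptm_type: str = "all",
    properties: Sequence[str] = PROPERTIES,
) -> list[CorrelationResult]:
    """Pearson correlation of per-protein PTM-site counts with each property."""
    common = [p for p in props.index if p in site_counts]
    if len(common) < 3:
        raise ValueError("need at least 3 proteins with both a site count and properties")
    counts = np.array([site_counts[p] for p in common], dtype=float)
    sub = props.loc[common]
    out = []
    for prop in properties:
        vals = sub[prop].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        x, y = counts[ok], vals[ok]
        if len(x) < 3 or x.std() == 0 or y.std() == 0:
            out.append(CorrelationResult(species, ptm_type, prop, math.nan, math.nan, len(x)))
            continue
        r, p = stats.pearsonr(x, y)
        out.append(CorrelationResult(species, ptm_type, prop, float(r), float(p), len(x)))
    return out
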