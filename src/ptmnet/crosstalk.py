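"""Cross-protein PTM interaction tests.

Do physically interacting protein pairs carry a particular combination of
PTM types more often than expected? Proteins are labeled with their PTM
type from the one-PTM-type-only sets (so each protein has exactly one
label), restricted to proteins present in the pruned interaction network,
and types with fewer than 10 such proteins are excluded. For a type pair
(a, b) — a may equal b — the 2x2 table crosses, over all unordered pairs
of labeled proteins, whether the pair's label multiset is {a, b} against
whether the pair is an interaction network edge. The test is one-sided
Fisher (enrichment); non-edges are counted within the labeled universe
only, making the test label-conditional. FDR is applied across all type
pairs within one species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Iterable

import pandas as pd

from ._stats import bh_adjust, fisher_enrichment_p
from .pin import InteractionNetwork
from .ptm_data import TypeProteinSets


@dataclass
class PairInteractionResult:
    species: int
    type_a: str
    type_b: str
    table: tuple[int, int, int, int]  # (combo&edge, combo&non-edge, other&edge, other&non-edge)
    n_proteins_a: int
    n_proteins_b: int
    p_raw: float = math.nan
    p_fdr: float = math.nan
    significant: bool = False


def eligible_universe(
    net: InteractionNetwork, sets: TypeProteinSets, min_proteins: int = 10
) -> dict[str, str]:
    """Map protein -> PTM-type label for the testable universe.

    Keeps proteins that are in the network and in exactly one type set;
    with one-PTM-type-only sets (the default input) the sets are already
    disjoint. Types ending up with fewer than ``min_proteins`` labeled
    proteins are removed wholesale.
    """
    nodes = net.nodes
    labels: dict[str, str] = {}
    ambiguous: set[str] = set()
    for t, proteins in sets.assignment.items():
        for p in proteins & nodes:
            if p in labels and labels[p] != t:
                ambiguous.add(p)
            else:
                labels[p] = t
    for p in ambiguous:
        labels.pop(p, None)
    counts = pd.Series(list(labels.values())).value_counts() if labels else pd.Series(dtype=int)
    small = {t for t, c in counts.items() if c < min_proteins}
    labels = {p: t for p, t in labels.items() if t not in small}
    if len(labels) < 2:
        raise ValueError("fewer than 2 labeled proteins; nothing to test")
    return labels


def pair_enrichment(
    labels: dict[str, str],
    net: InteractionNetwork,
    type_a: str,
    type_b: str,
    alternative: str = "greater",
) -> PairInteractionResult:
    """Fisher test of label-combination {a, b} against interaction status."""
    proteins = list(labels)
    m = len(proteins)
    total_pairs = m * (m - 1) // 2
    n_a = sum(1 for t in labels.values() if t == type_a)
    n_b = sum(1 for t in labels.values() if t == type_b)
    if type_a == type_b:
        combo_pairs = n_a * (n_a - 1) // 2
    else:
        combo_pairs = n_a * n_b
    # edges within the labeled universe, split by label combination
    labeled_edges = 0
    combo_edges = 0
    want = frozenset((type_a, type_b))
    for u, v in net.graph.edges:
        lu, lv = labels.get(u), labels.get(v)
        if lu is None or lv is None:
            continue
        labeled_edges += 1
        if frozenset((lu, lv)) == want:
            combo_edges += 1
    table = (
        combo_edges,
        combo_pairs - combo_edges,
        labeled_edges - combo_edges,
        total_pairs - combo_pairs - (labeled_edges - combo_edges),
    )
    res = PairInteractionResult(
        species=net.species,
        type_a=type_a,
        type_b=type_b,
        table=table,
        n_proteins_a=n_a,
        n_proteins_b=n_b,
    )
    if combo_pairs == 0:
        res.p_raw = 1.0
        return res
    if alternative == "greater":
        res.p_raw = fisher_enrichment_p(combo_edges, total_pairs, combo_pairs, labeled_edges)
    else:
        from scipy.stats import fisher_exact

        res.p_raw = float(
            fisher_exact([[table[0], table[1]], [table[2], table[3]]], alternative)[1]
        )
    return res


def test_species(
    net: InteractionNetwork,
    sets: TypeProteinSets,
    min_proteins: int = 10,
    alpha: float = 0.01,
    alternative: str = "greater",
) -> list[PairInteractionResult]:
    """All type-pair interaction tests (self-pairs included) for one species."""
    labels = eligible_universe(net, sets, min_proteins)
    types = sorted(set(labels.values()))
    results = [
        pair_enrichment(labels, net, a, b, alternative)
        for a, b in combinations_with_replacement(types, 2)
    ]
    adj = bh_adjust([r.p_raw for r in results])
    for r, q in zip(results, adj):
        r.p_fdr = float(q)
        r.significant = bool(q < alpha)
    return results


def crosstalk_network(results_by_species: Iterable[list[PairInteractionResult]]) -> pd.DataFrame:
    """Cross-species summary: per type pair, #species significant / #common."""
    rows: dict[tuple[str, str], dict] = {}
    for results in results_by_species:
        for r in results:
            key = tuple(sorted((r.type_a, r.type_b)))
            rec = rows.setdefault(
                key, {"type_a": key[0], "type_b": key[1], "n_significant": 0, "n_common": 0}
            )
            rec["n_common"] += 1
            rec["n_significant"] += int(r.significant)
    df = pd.DataFrame(list(rows.values()))
    if not df.empty:
        df["label"] = df.apply(lambda r: f"{r.n_significant} ({r.n_common})", axis=1)
        df = df[df["n_significant"] > 0].sort_values(["type_a", "type_b"]).reset_index(drop=True)
    return df


def results_frame(results: Iterable[PairInteractionResult]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in results])
    if not df.empty:
        df[["n_combo_edge", "n_combo_nonedge", "n_other_edge", "n_other_nonedge"]] = pd.DataFrame(
            df.pop("table").tolist(), index=df.index
        )
    return df
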