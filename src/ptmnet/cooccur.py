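"""Co-existence of PTM-type pairs on the same proteins.

Within one species, each pair of PTM types is scored by the Jaccard index
of their carrier protein sets and tested for greater-than-chance overlap
with a one-sided Fisher exact test over the species' PTM-carrying proteome
(or, optionally, a supplied full-proteome universe). P-values are BH-FDR
adjusted over all type pairs of the species; an edge is called significant
when the adjusted p is below 0.01 and the observed overlap exceeds its
expectation under independence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import pandas as pd

from ._stats import bh_adjust, fisher_enrichment_p
from .ptm_data import TypeProteinSets


@dataclass
class CoexistenceEdge:
    species: int
    type_a: str
    type_b: str
    jaccard: float
    overlap_count: int
    size_a: int
    size_b: int
    universe_size: int
    p_raw: float = math.nan
    p_fdr: float = math.nan
    significant: bool = False

    @property
    def expected_overlap(self) -> float:
        return self.size_a * self.size_b / self.universe_size


def jaccard(set_a: set, set_b: set) -> float:
    """|A n B| / |A u B|; undefined (NaN) when both sets are empty."""
    union = len(set_a | set_b)
    if union == 0:
        return math.nan
    return len(set_a & set_b) / union


def coexistence_test(
    set_a: set,
    set_b: set,
    universe: set,
    species: int = 0,
    type_a: str = "A",
    type_b: str = "B",
) -> CoexistenceEdge:
    """One-sided Fisher test of the 2x2 [in A?] x [in B?] table."""
    if not (set_a | set_b) <= universe:
        raise ValueError("universe must contain the union of both sets")
    a, b = set_a & universe, set_b & universe
    k = len(a & b)
    edge = CoexistenceEdge(
        species=species,
        type_a=type_a,
        type_b=type_b,
        jaccard=jaccard(a, b),
        overlap_count=k,
        size_a=len(a),
        size_b=len(b),
        universe_size=len(universe),
    )
    edge.p_raw = fisher_enrichment_p(k, len(universe), len(a), len(b))
    return edge


def test_species(
    sets: TypeProteinSets,
    universe: set | None = None,
    alpha: float = 0.01,
) -> list[CoexistenceEdge]:
    """All pairwise co-existence tests for one species, FDR-adjusted.

    The default universe is the species' own PTM-carrying proteome (every
    protein with at least one retained modification); pass ``universe``
    explicitly to test against a full-proteome background instead.
    """
    if universe is None:
        universe = sets.proteins()
    types = sets.types()
    edges = [
        coexistence_test(
            sets.assignment[a], sets.assignment[b], universe, sets.species, a, b
        )
        for a, b in combinations(types, 2)
    ]
    adj = bh_adjust([e.p_raw for e in edges])
    for e, q in zip(edges, adj):
        e.p_fdr = float(q)
        e.significant = bool(q < alpha and e.overlap_count > e.expected_overlap)
    return edges


def cross_species_summary(edges: Iterable[CoexistenceEdge]) -> pd.DataFrame:
    """Per type-pair: species significant, common species, and their ratio.

    A species counts as "common" for a pair whenever the pair was testable
    there (both types passed the upstream filters and produced an edge).
    Pairs with no common species are omitted.
    """
    rows: dict[tuple[str, str], dict] = {}
    for e in edges:
        key = tuple(sorted((e.type_a, e.type_b)))
        rec = rows.setdefault(
            key, {"type_a": key[0], "type_b": key[1], "n_significant": 0, "n_common": 0}
        )
        rec["n_common"] += 1
        rec["n_significant"] += int(e.significant)
    df = pd.DataFrame(list(rows.values()))
    if not df.empty:
        df["ratio"] = df["n_significant"] / df["n_common"]
        df = df.sort_values(["type_a", "type_b"]).reset_index(drop=True)
    return df


def edges_frame(edges: Iterable[CoexistenceEdge]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in edges])
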