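"""Loading, consolidation and filtering of PTM site records.

The unit of information is one experimentally verified modification site on
one protein. Records from several source databases describing the same site
(same species, protein, sequence position and modification type) are
consolidated into a single record carrying the union of source labels.
Downstream analyses work on per-species protein sets per PTM type, either
including every carrier (``all`` mode), only proteins carrying exactly one
PTM type (``one-type-only``), or keyed by subtype (``subtype``).
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The twelve modification types abundant enough for network analysis.
CONTROLLED_PTM_TYPES = (
    "acetylation",
    "amidation",
    "carboxylation",
    "disulfide bond",
    "glycosylation",
    "hydroxylation",
    "methylation",
    "nitrosylation",
    "phosphorylation",
    "proteolytic cleavage",
    "sumoylation",
    "ubiquitination",
)

MODES = ("all", "one-type-only", "subtype")


@dataclass(frozen=True)
class PTMRecord:
    """One experimentally verified modification site.

    ``position`` is 1-based on the protein sequence; ``residue`` is a
    one-letter amino-acid code or ``"-"`` when the residue is not tied to a
    single position (e.g. N-terminal acetylation). ``residue_claims`` keeps
    every residue reported by any source when sources disagree.
    """

    species: int
    protein_id: str
    position: int
    ptm_type: str
    residue: str = "-"
    ptm_subtype: str | None = None
    sources: tuple[str, ...] = ()
    experimental: bool = True
    residue_claims: tuple[str, ...] = ()

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if not self.ptm_type:
            raise ValueError("ptm_type must be non-empty")

    @property
    def key(self) -> tuple[int, str, int, str]:
        """Consolidation key: (species, protein, position, type)."""
        return (self.species, self.protein_id, self.position, self.ptm_type)


@dataclass
class PTMDataset:
    """A consolidated, filterable collection of PTM records."""

    records: list[PTMRecord]
    protein_lengths: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def species(self) -> set[int]:
        return {r.species for r in self.records}

    def site_counts_by_type(self) -> Counter:
        """Global (all-species) site count per PTM type."""
        return Counter(r.ptm_type for r in self.records)

    def site_counts_by_species(self) -> Counter:
        return Counter(r.species for r in self.records)

    def sites_per_protein(self, species: int) -> Counter:
        """Distinct consolidated sites per protein, all PTM types pooled."""
        c: Counter = Counter()
        for r in self.records:
            if r.species == species:
                c[r.protein_id] += 1
        return c

    def subset(self, keep) -> "PTMDataset":
        kept = [r for r in self.records if keep(r)]
        return PTMDataset(kept, dict(self.protein_lengths))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxid": [r.species for r in self.records],
                "protein_id": [r.protein_id for r in self.records],
                "position": [r.position for r in self.records],
                "residue": [r.residue for r in self.records],
                "ptm_type": [r.ptm_type for r in self.records],
                "ptm_subtype": [r.ptm_subtype or "" for r in self.records],
                "source_db": [";".join(r.sources) for r in self.records],
                "experimental": [int(r.experimental) for r in self.records],
            }
        )


@dataclass
class TypeProteinSets:
    """Per-species map from PTM type (or subtype) to its carrier protein set."""

    species: int
    assignment: dict[str, set[str]]
    mode: str = "all"

    def types(self) -> list[str]:
        return sorted(self.assignment)

    def proteins(self) -> set[str]:
        out: set[str] = set()
        for s in self.assignment.values():
            out |= s
        return out


@dataclass
class AbundanceResult:
    dataset: PTMDataset
    retained_types: list[str]
    retained_species: list[int]


# ---------------------------------------------------------------------------
# loading

def load_ptm_tsv(path: str | Path, id_map: Mapping[str, str] | None = None) -> list[PTMRecord]:
    """Read raw PTM records from the tab-separated exchange format.

    Columns: taxid, protein_id, position, residue, ptm_type, ptm_subtype,
    source_db, experimental (0/1). Lines starting with ``#`` are comments.
    Malformed rows are skipped with a per-row diagnostic. When ``id_map``
    is given it is applied verbatim before consolidation; unmapped IDs are
    dropped (count logged).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    records: list[PTMRecord] = []
    bad = 0
    unmapped = 0
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            pid = row.protein_id
            if id_map is not None:
                if pid not in id_map:
                    unmapped += 1
                    continue
                pid = id_map[pid]
            records.append(
                PTMRecord(
                    species=int(row.taxid),
                    protein_id=pid,
                    position=int(row.position),
                    residue=row.residue or "-",
                    ptm_type=row.ptm_type,
                    ptm_subtype=row.ptm_subtype or None,
                    sources=(row.source_db,) if row.source_db else (),
                    experimental=bool(int(row.experimental)),
                )
            )
        except (ValueError, TypeError) as exc:
            bad += 1
            logger.warning("skipping malformed PTM row %d: %s", i, exc)
    if bad:
        logger.warning("skipped %d malformed PTM rows", bad)
    if unmapped:
        logger.info("dropped %d records with unmapped protein IDs", unmapped)
    return records


def load_lengths_tsv(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"protein_id": str, "length": int})
    return dict(zip(df["protein_id"], df["length"]))


def load_id_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


# ---------------------------------------------------------------------------
# consolidation & filtering

def consolidate(
    records: Iterable[PTMRecord],
    protein_lengths: Mapping[str, int] | None = None,
) -> PTMDataset:
    """Merge multi-source records into one per (species, protein, position, type).

    Non-experimental records are dropped at ingest. Source labels are
    unioned; conflicting residue claims at the same site are kept (all
    claims retained, first seen wins as the representative) with a warning.
    """
    merged: dict[tuple, PTMRecord] = {}
    dropped_pred = 0
    merged_count = 0
    residue_conflicts = 0
    for rec in records:
        if not rec.experimental:
            dropped_pred += 1
            continue
        key = rec.key
        if key not in merged:
            claims = rec.residue_claims or ((rec.residue,) if rec.residue != "-" else ())
            merged[key] = replace(rec, residue_claims=claims)
            continue
        merged_count += 1
        old = merged[key]
        sources = tuple(dict.fromkeys(old.sources + rec.sources))
        claims = old.residue_claims
        if rec.residue != "-" and rec.residue not in claims:
            if claims:
                residue_conflicts += 1
            claims = claims + (rec.residue,)
        subtype = old.ptm_subtype or rec.ptm_subtype
        merged[key] = replace(old, sources=sources, residue_claims=claims, ptm_subtype=subtype)
    if dropped_pred:
        logger.info("dropped %d non-experimental records", dropped_pred)
    if merged_count:
        logger.info("merged %d duplicate records", merged_count)
    if residue_conflicts:
        logger.warning("%d sites have conflicting residue claims between sources", residue_conflicts)
    return PTMDataset(list(merged.values()), dict(protein_lengths or {}))


def abundance_filter(
    dataset: PTMDataset, type_min: int = 1000, species_min: int = 1000
) -> AbundanceResult:
    """Keep abundant PTM types and species.

    A PTM type is retained iff its global site count is strictly greater
    than ``type_min``; a species is retained iff its site count across the
    retained types is at least ``species_min``. The intersection defines
    the primary type-by-species working dataset.
    """
    if not dataset.records:
        logger.warning("abundance_filter called on an empty dataset")
        return AbundanceResult(PTMDataset([], dict(dataset.protein_lengths)), [], [])
    by_type = dataset.site_counts_by_type()
    retained_types = sorted(t for t, c in by_type.items() if c > type_min)
    by_species: Counter = Counter()
    for r in dataset.records:
        if r.ptm_type in retained_types:
            by_species[r.species] += 1
    retained_species = sorted(s for s, c in by_species.items() if c >= species_min)
    tset, sset = set(retained_types), set(retained_species)
    working = dataset.subset(lambda r: r.ptm_type in tset and r.species in sset)
    return AbundanceResult(working, retained_types, retained_species)


def _length_outliers(lengths: np.ndarray, ids: list[str]) -> set[str]:
    """Proteins strictly below the 1st or above the 99th length percentile."""
    lo, hi = np.percentile(lengths, [1, 99])  # linear interpolation ("type 7")
    return {pid for pid, ln in zip(ids, lengths) if ln < lo or ln > hi}


def outlier_filter(dataset: PTMDataset, per_species: bool = True) -> PTMDataset:
    """Remove extreme-length proteins and heavily modified outlier proteins.

    Per species: proteins whose sequence length falls strictly below the
    1st or above the 99th percentile of the observed length distribution
    are removed first; then proteins whose total site count is >= mean +
    3*sd (sample sd) of the per-protein site-count distribution are removed,
    with mean/sd computed after length removal. Species with fewer than
    three observed proteins are left untouched.
    """
    if not dataset.protein_lengths:
        logger.warning("no protein lengths supplied; skipping length-outlier filter")

    drop: set[tuple[int, str]] = set()
    species_list = sorted(dataset.species) if per_species else [None]
    for sp in species_list:
        recs = [r for r in dataset.records if per_species is False or r.species == sp]
        proteins = sorted({r.protein_id for r in recs})
        if len(proteins) < 3:
            logger.warning("species %s has <3 proteins; outlier filters skipped", sp)
            continue
        removed: set[str] = set()
        if dataset.protein_lengths:
            with_len = [p for p in proteins if p in dataset.protein_lengths]
            if len(with_len) >= 3:
                lengths = np.array([dataset.protein_lengths[p] for p in with_len], dtype=float)
                removed = _length_outliers(lengths, with_len)
        survivors = [p for p in proteins if p not in removed]
        counts = Counter(r.protein_id for r in recs if r.protein_id in set(survivors))
        vals = np.array([counts[p] for p in survivors], dtype=float)
        if vals.size >= 3:
            sd = vals.std(ddof=1)
            if sd > 0:  # zero spread: no protein is an outlier
                cutoff = vals.mean() + 3 * sd
                removed |= {p for p in survivors if counts[p] >= cutoff}
        for p in removed:
            for r in recs:
                if r.protein_id == p:
                    drop.add((r.species, p))
    out = dataset.subset(lambda r: (r.species, r.protein_id) not in drop)
    logger.info("outlier_filter removed %d records", len(dataset) - len(out))
    return out


def build_type_sets(dataset: PTMDataset, mode: str = "all") -> dict[int, TypeProteinSets]:
    """Build per-species protein sets per PTM type (or subtype).

    ``all``: a protein appears in every type set it has a record for.
    ``one-type-only``: a protein is retained only if it carries exactly one
    distinct PTM type — the per-type sets are then pairwise disjoint.
    ``subtype``: sets keyed by ``ptm_subtype`` (records without a subtype
    are ignored).
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    per_species: dict[int, dict[str, set[str]]] = defaultdict(lambda: defaultdict(set))
    types_per_protein: dict[tuple[int, str], set[str]] = defaultdict(set)
    for r in dataset.records:
        types_per_protein[(r.species, r.protein_id)].add(r.ptm_type)
    for r in dataset.records:
        if mode == "subtype":
            if r.ptm_subtype:
                per_species[r.species][r.ptm_subtype].add(r.protein_id)
            continue
        if mode == "one-type-only" and len(types_per_protein[(r.species, r.protein_id)]) != 1:
            continue
        per_species[r.species][r.ptm_type].add(r.protein_id)
    return {
        sp: TypeProteinSets(sp, {t: set(s) for t, s in assign.items()}, mode)
        for sp, assign in per_species.items()
    }
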