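"""GO-term enrichment per PTM type and disease-overlap quartile tests.

Enrichment uses the one-sided Fisher exact test per term on the annotation
closure (a protein annotated to a term is annotated to all its is_a
ancestors). Two methods are provided: ``classic`` tests every term
independently; ``elim`` decorrelates the DAG by walking terms from the
leaves upward and, whenever a term is significant at the raw cutoff,
removing its study genes from the gene lists of all strict ancestors
before those are tested. Adjusted p-values (BH-FDR) are computed per
namespace over the resulting raw p's.

The disease operations test whether proteins in the top or bottom quartile
of a network property, within one PTM type's carrier set, overlap human
disease proteins more than expected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import obonet
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist

from ._stats import bh_adjust, fisher_enrichment_p

logger = logging.getLogger(__name__)

NAMESPACES = ("process", "function", "component")


@dataclass
class GoDag:
    """A minimal GO-style DAG (is_a only) plus protein annotations."""

    terms: dict[str, dict]                      # id -> {"name": ..., "namespace": ...}
    parents: dict[str, frozenset]               # id -> is_a parents
    annotations: dict[str, set] = field(default_factory=dict)  # protein -> terms
    closed: bool = False

    def namespace(self, term: str) -> str:
        return self.terms[term].get("namespace", "process")

    def ancestors(self, term: str) -> set:
        """All strict is_a ancestors of ``term``."""
        out: set = set()
        stack = list(self.parents.get(term, ()))
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.parents.get(t, ()))
        return out

    def check_acyclic(self) -> None:
        ts = TopologicalSorter({t: set(self.parents.get(t, ())) for t in self.terms})
        try:
            ts.prepare()
        except CycleError as exc:
            cycle = exc.args[1]
            raise ValueError(f"cycle detected in DAG: {cycle[0]} -> {cycle[1]}") from exc


@dataclass
class EnrichmentResult:
    """Generic Fisher-test outcome, reused by GO and disease tests."""

    label: str
    study_count: int
    study_size: int
    bg_count: int
    bg_size: int
    p_raw: float = math.nan
    p_fdr: float = math.nan
    method: str = "classic"
    namespace: str = ""
    name: str = ""
    tested: bool = True


# ---------------------------------------------------------------------------
# I/O

def load_obo(path: str | Path) -> GoDag:
    """Read an OBO-lite ontology (id, name, namespace, is_a) via obonet.

    Relationship types other than is_a are ignored with a warning.
    """
    g = obonet.read_obo(path)
    terms: dict[str, dict] = {}
    parents: dict[str, frozenset] = {}
    other_rels = 0
    for node, data in g.nodes(data=True):
        terms[node] = {
            "name": data.get("name", node),
            "namespace": _short_namespace(data.get("namespace", "process")),
        }
    for child, parent, key in g.edges(keys=True):
        if key != "is_a":
            other_rels += 1
            continue
        parents[child] = parents.get(child, frozenset()) | {parent}
    if other_rels:
        logger.warning("ignored %d non-is_a relationships", other_rels)
    return GoDag(terms, parents)


def _short_namespace(ns: str) -> str:
    return {"biological_process": "process", "molecular_function": "function",
            "cellular_component": "component"}.get(ns, ns)


def load_gaf(path: str | Path) -> dict[str, set]:
    """Two-column GAF-like annotation table: protein_id, go_id."""
    df = pd.read_csv(path, sep="\t", comment="!", header=None, dtype=str,
                     names=["protein_id", "go_id"])
    ann: dict[str, set] = {}
    for pid, go in zip(df["protein_id"], df["go_id"]):
        ann.setdefault(pid, set()).add(go)
    return ann


def load_disease_list(path: str | Path) -> set:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}


# ---------------------------------------------------------------------------
# closure & enrichment

def annotation_closure(dag: GoDag) -> GoDag:
    """Close every protein's term set under is_a ancestors. Idempotent."""
    dag.check_acyclic()
    unknown = {t for ts in dag.annotations.values() for t in ts} - set(dag.terms)
    if unknown:
        raise ValueError(f"annotations reference unknown terms: {sorted(unknown)[:5]}")
    anc_cache = {t: dag.ancestors(t) for t in dag.terms}
    closed = {
        prot: set().union(ts, *(anc_cache[t] for t in ts))
        for prot, ts in dag.annotations.items()
    }
    return GoDag(dag.terms, dag.parents, closed, closed=True)


def _elim_order(dag: GoDag, terms: Sequence[str]) -> list[str]:
    """Terms by increasing longest-path depth from the leaves, ties by id."""
    children: dict[str, set] = {t: set() for t in terms}
    tset = set(terms)
    for child, ps in dag.parents.items():
        if child in tset:
            for p in ps:
                if p in tset:
                    children[p].add(child)
    depth: dict[str, int] = {}

    def _depth(t: str) -> int:
        if t not in depth:
            depth[t] = 0 if not children[t] else 1 + max(_depth(c) for c in children[t])
        return depth[t]

    for t in terms:
        _depth(t)
    return sorted(terms, key=lambda t: (depth[t], t))


def go_enrich(
    study: set,
    background: set,
    dag: GoDag,
    method: str = "classic",
    alpha: float = 0.01,
    namespaces: Sequence[str] = NAMESPACES,
) -> list[EnrichmentResult]:
    """Per-term Fisher enrichment of ``study`` within ``background``.

    ``alpha`` is the raw-p elimination cutoff used by ``elim`` only. FDR is
    applied per namespace over the resulting raw p-values, and results are
    returned sorted by adjusted p (ties by term id). Terms with zero
    background count are skipped.
    """
    if not study:
        raise ValueError("study set is empty")
    if not study <= background:
        raise ValueError("study must be a subset of background")
    if method not in ("classic", "elim"):
        raise ValueError(f"unknown method {method!r}")
    cdag = dag if dag.closed else annotation_closure(dag)
    term_proteins: dict[str, set] = {t: set() for t in cdag.terms}
    for prot, ts in cdag.annotations.items():
        if prot in background:
            for t in ts:
                term_proteins[t].add(prot)

    results: list[EnrichmentResult] = []
    big_n, n = len(background), len(study)
    for ns in namespaces:
        ns_terms = [t for t in cdag.terms if cdag.namespace(t) == ns and term_proteins[t]]
        removed: dict[str, set] = {t: set() for t in ns_terms}
        order = _elim_order(cdag, ns_terms) if method == "elim" else sorted(ns_terms)
        ns_results = []
        for t in order:
            bg_genes = term_proteins[t] - removed[t]
            study_genes = bg_genes & study
            big_k, k = len(bg_genes), len(study_genes)
            # fully eliminated terms are still reported (p = 1 by the tail)
            p = fisher_enrichment_p(k, big_n, big_k, n)
            ns_results.append(
                EnrichmentResult(
                    label=t, study_count=k, study_size=n, bg_count=big_k, bg_size=big_n,
                    p_raw=p, method=method, namespace=ns, name=cdag.terms[t]["name"],
                )
            )
            if method == "elim" and p < alpha:
                for anc in cdag.ancestors(t):
                    if anc in removed:
                        removed[anc] |= study_genes
        adj = bh_adjust([r.p_raw for r in ns_results])
        for r, q in zip(ns_results, adj):
            r.p_fdr = float(q)
        results.extend(ns_results)
    results.sort(key=lambda r: (r.p_fdr if not math.isnan(r.p_fdr) else 2.0, r.label))
    return results


def top_terms_matrix(
    results_by_type: Mapping[str, list[EnrichmentResult]],
    k: int = 5,
    sig_level: float = 0.01,
) -> pd.DataFrame:
    """Union of each type's top-k significant terms as a -log10(p_fdr) matrix.

    Cells are 0 where the term is not significant for that type. Rows and
    columns are ordered by agglomerative average-linkage clustering with
    Euclidean distance (single row/column: natural order). Leaf order is
    deterministic: inputs are pre-sorted by label so distance ties resolve
    identically across runs. Dendrogram leaf orders are stored in
    ``df.attrs["row_order"]`` / ``df.attrs["col_order"]``.
    """
    chosen: set[str] = set()
    names: dict[str, str] = {}
    for t, results in results_by_type.items():
        sig = [r for r in results if not math.isnan(r.p_fdr) and r.p_fdr < sig_level]
        sig.sort(key=lambda r: (r.p_fdr, r.label))
        for r in sig[:k]:
            chosen.add(r.label)
            names[r.label] = r.name
    if not chosen:
        logger.warning("no significant terms for any PTM type; empty matrix")
        return pd.DataFrame()
    rows = sorted(chosen)
    cols = sorted(results_by_type)
    mat = pd.DataFrame(0.0, index=rows, columns=cols)
    for t, results in results_by_type.items():
        for r in results:
            if r.label in chosen and not math.isnan(r.p_fdr) and r.p_fdr < sig_level:
                mat.loc[r.label, t] = -math.log10(max(r.p_fdr, 1e-300))

    def _order(frame: pd.DataFrame) -> list[int]:
        if len(frame) < 2:
            return list(range(len(frame)))
        z = average(pdist(frame.to_numpy(), metric="euclidean"))
        return list(leaves_list(z))

    row_order, col_order = _order(mat), _order(mat.T)
    out = mat.iloc[row_order, col_order]
    out.attrs["row_order"] = [rows[i] for i in row_order]
    out.attrs["col_order"] = [cols[i] for i in col_order]
    out.attrs["term_names"] = names
    return out


# ---------------------------------------------------------------------------
# disease overlap

def disease_overlap_test(
    props: pd.DataFrame,
    ptm_set: set,
    disease_proteins: set,
    property: str,
    tail: str = "top",
    q: float = 0.25,
    quantile_ref: str = "ptm",
) -> EnrichmentResult:
    """Fisher test: property-tail membership x disease membership.

    The tail set holds the PTM-carrying network proteins whose property
    value lies in the top (or bottom) ``q`` quantile; by default quantiles
    are taken within the focal PTM set's own value distribution
    (``quantile_ref="global"`` uses the whole network instead). The test
    universe is the full property-table (network) universe.
    """
    if tail not in ("top", "bottom"):
        raise ValueError("tail must be 'top' or 'bottom'")
    universe = set(props.index)
    vals = props[property]
    members = sorted(ptm_set & universe)
    mvals = vals.loc[members].dropna()
    label = f"{property}:{tail}"
    if mvals.empty:
        return EnrichmentResult(label, 0, 0, len(disease_proteins & universe),
                                len(universe), method="disease", tested=False)
    ref = mvals if quantile_ref == "ptm" else vals.dropna()
    if tail == "top":
        cut = float(np.quantile(ref.to_numpy(), 1 - q))
        tail_set = set(mvals.index[mvals >= cut])
    else:
        cut = float(np.quantile(ref.to_numpy(), q))
        tail_set = set(mvals.index[mvals <= cut])
    if not tail_set:
        return EnrichmentResult(label, 0, 0, len(disease_proteins & universe),
                                len(universe), method="disease", tested=False)
    disease_in = disease_proteins & universe
    k = len(tail_set & disease_in)
    res = EnrichmentResult(
        label=label,
        study_count=k,
        study_size=len(tail_set),
        bg_count=len(disease_in),
        bg_size=len(universe),
        method="disease",
    )
    res.p_raw = fisher_enrichment_p(k, len(universe), len(disease_in), len(tail_set))
    return res


def disease_tests(
    props: pd.DataFrame,
    type_sets: Mapping[str, set],
    disease_proteins: set,
    properties: Sequence[str] = ("degree", "clustering", "closeness"),
    q: float = 0.25,
    quantile_ref: str = "ptm",
) -> pd.DataFrame:
    """Full quartile-test grid: PTM types x properties x {top, bottom}.

    One BH family across all PTM types and network properties.
    """
    rows = []
    for ptm_type, pset in sorted(type_sets.items()):
        for prop in properties:
            for tail in ("top", "bottom"):
                r = disease_overlap_test(
                    props, pset, disease_proteins, prop, tail, q, quantile_ref
                )
                rows.append({"ptm_type": ptm_type, **vars(r)})
    df = pd.DataFrame(rows)
    df["p_fdr"] = bh_adjust(df["p_raw"].to_numpy())
    return df


def results_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
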