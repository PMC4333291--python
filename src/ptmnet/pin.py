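"""Protein interaction networks and node-level topology metrics.

Networks are undirected simple graphs over protein identifiers with an edge
confidence in [0, 1]. Only high-confidence edges (default >= 0.9) enter the
analysis, and connected components smaller than 100 proteins are pruned,
which in practice leaves the giant component. Three unweighted metrics are
computed per protein:

* degree ``k_n`` — the number of edges incident to the node;
* clustering coefficient ``C_n = 2 e_n / (k_n (k_n - 1))`` with ``e_n`` the
  number of connected pairs among the node's neighbours, undefined for
  ``k_n < 2``;
* closeness centrality ``C_c(n) = 1 / sum_m L(n, m)``, the reciprocal of the
  summed unweighted shortest-path lengths to every other node of the node's
  connected component (unnormalised).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

DIALECTS = ("string-tsv", "mitab-min")


@dataclass
class InteractionNetwork:
    """Undirected simple protein graph with per-edge confidence."""

    graph: nx.Graph
    species: int = 0
    source_label: str = "synthetic"

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a, b)

    def copy(self) -> "InteractionNetwork":
        return InteractionNetwork(self.graph.copy(), self.species, self.source_label)


def from_edges(
    edges,
    species: int = 0,
    source_label: str = "synthetic",
    min_confidence: float = 0.0,
) -> InteractionNetwork:
    """Build a network from (a, b, confidence) triples.

    Self-loops are dropped; duplicate and reversed-duplicate edges are
    merged keeping the maximum confidence; edges below ``min_confidence``
    are discarded after merging.
    """
    g = nx.Graph()
    self_loops = 0
    for a, b, conf in edges:
        if a == b:
            self_loops += 1
            continue
        if g.has_edge(a, b):
            g[a][b]["confidence"] = max(g[a][b]["confidence"], conf)
        else:
            g.add_edge(a, b, confidence=float(conf))
    if self_loops:
        logger.info("dropped %d self-loops", self_loops)
    if min_confidence > 0:
        low = [(a, b) for a, b, c in g.edges(data="confidence") if c < min_confidence]
        g.remove_edges_from(low)
        g.remove_nodes_from(list(nx.isolates(g)))
    if g.number_of_edges() == 0:
        logger.warning("network has zero edges after filtering")
    return InteractionNetwork(g, species, source_label)


def _parse_string_tsv(path: Path):
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                logger.warning("%s:%d: expected 3 columns, skipping", path, lineno)
                continue
            try:
                score = float(parts[2])
            except ValueError:
                if lineno == 1:  # header row autodetected
                    continue
                logger.warning("%s:%d: unparsable score %r, skipping", path, lineno, parts[2])
                continue
            rows.append((parts[0], parts[1], score))
    # STRING native scores are integers on a 0-999 scale
    if rows and any(s > 1.0 for _, _, s in rows):
        rows = [(a, b, s / 1000.0) for a, b, s in rows]
        logger.info("scores >1 detected; interpreted as STRING 0-999 scale and divided by 1000")
    return rows


def _parse_mitab_min(path: Path):
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                logger.warning("%s:%d: expected >=2 columns, skipping", path, lineno)
                continue
            # "id:value" prefixes stripped at the first colon
            a = parts[0].split(":", 1)[-1]
            b = parts[1].split(":", 1)[-1]
            score = 1.0  # curated binary interactions count as verified
            if len(parts) >= 15 and parts[14]:
                try:
                    score = float(parts[14].rsplit(":", 1)[-1])
                except ValueError:
                    pass
            rows.append((a, b, score))
    return rows


def load_network(
    path: str | Path,
    dialect: str = "string-tsv",
    min_confidence: float = 0.9,
    species: int = 0,
    source_label: str | None = None,
) -> InteractionNetwork:
    """Load an edge list in the given dialect and confidence-filter it."""
    path = Path(path)
    if dialect == "string-tsv":
        rows = _parse_string_tsv(path)
    elif dialect == "mitab-min":
        rows = _parse_mitab_min(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    label = source_label or ("STRING" if dialect == "string-tsv" else "IntAct")
    return from_edges(rows, species=species, source_label=label, min_confidence=min_confidence)


def prune_components(net: InteractionNetwork, min_size: int = 100) -> InteractionNetwork:
    """Drop connected components with fewer than ``min_size`` nodes."""
    g = net.graph
    keep = [c for c in nx.connected_components(g) if len(c) >= min_size]
    if not keep:
        logger.warning("all components below min_size=%d; network is empty", min_size)
        return InteractionNetwork(nx.Graph(), net.species, net.source_label)
    kept_nodes = set().union(*keep)
    out = InteractionNetwork(g.subgraph(kept_nodes).copy(), net.species, net.source_label)
    if len(keep) == 1:
        logger.info("one (giant) component of %d nodes remains", len(kept_nodes))
    return out


# ---------------------------------------------------------------------------
# metrics

def degree(net: InteractionNetwork, n: str) -> int:
    if n not in net.graph:
        raise KeyError(f"node {n!r} not in network")
    return net.graph.degree(n)


def clustering_coefficient(
    net: InteractionNetwork, n: str, undefined_as_zero: bool = False
) -> float | None:
    """``2 e_n / (k_n (k_n - 1))``; ``None`` (undefined) for degree < 2.

    With ``undefined_as_zero`` the 0-convention used by some packages is
    applied instead of flagging the value as undefined.
    """
    if n not in net.graph:
        raise KeyError(f"node {n!r} not in network")
    if net.graph.degree(n) < 2:
        return 0.0 if undefined_as_zero else None
    return float(nx.clustering(net.graph, n))


def closeness_centrality(net: InteractionNetwork, n: str, normalized: bool = False) -> float:
    """Reciprocal of the summed shortest-path lengths within n's component.

    ``normalized`` multiplies by (component size - 1), the convention used
    by igraph/networkx; fold changes are invariant to the choice.
    """
    if n not in net.graph:
        raise KeyError(f"node {n!r} not in network")
    lengths = nx.single_source_shortest_path_length(net.graph, n)
    total = sum(lengths.values())
    if total == 0:
        raise ValueError(f"closeness undefined for isolated node {n!r}")
    c = 1.0 / total
    return c * (len(lengths) - 1) if normalized else c


def property_table(
    net: InteractionNetwork,
    properties: tuple[str, ...] = ("degree", "clustering", "closeness"),
    undefined_clustering_as_zero: bool = False,
) -> pd.DataFrame:
    """One row per node: degree, clustering, closeness, component_id.

    Clustering is NaN where undefined (degree < 2) unless the 0-convention
    is requested. Component ids number components by decreasing size, ties
    broken by smallest member label.
    """
    g = net.graph
    nodes = sorted(g.nodes)
    if not nodes:
        return pd.DataFrame(
            columns=["degree", "clustering", "closeness", "component_id"]
        ).rename_axis("protein_id")
    data: dict[str, dict] = {}
    if "degree" in properties:
        data["degree"] = dict(g.degree)
    if "clustering" in properties:
        cl = nx.clustering(g)
        if not undefined_clustering_as_zero:
            cl = {n: (v if g.degree(n) >= 2 else math.nan) for n, v in cl.items()}
        data["clustering"] = cl
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    comp_id = {n: i for i, c in enumerate(comps) for n in c}
    if "closeness" in properties:
        from scipy.sparse.csgraph import shortest_path

        clo: dict[str, float] = {}
        for comp in comps:
            members = sorted(comp)
            adj = nx.to_scipy_sparse_array(g.subgraph(members), nodelist=members, weight=None)
            dist = shortest_path(adj, method="D", unweighted=True)
            totals = dist.sum(axis=1)
            for n, total in zip(members, totals):
                clo[n] = 1.0 / total if total else math.nan
        data["closeness"] = clo
    df = pd.DataFrame(index=pd.Index(nodes, name="protein_id"))
    for col in ("degree", "clustering", "closeness"):
        if col in data:
            df[col] = pd.Series(data[col])
    df["component_id"] = pd.Series(comp_id)
    return df


def write_property_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", na_rep="")
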