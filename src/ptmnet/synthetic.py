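"""Synthetic generator for every pipeline input, with controllable planted structure.

The generator stands in for the database exports the analysis was designed
around: a scale-free interaction network, multi-source experimental PTM
site records, a toy GO DAG with annotations, and a disease-protein list.
Each planted effect maps onto exactly one downstream statistic:

* degree bias ``beta`` — the probability that a protein carries PTM type t
  is proportional to ``(k+1)^beta`` (k its network degree), planting the
  "modified proteins have more interactions" signal;
* pairwise coupling ``rho`` — with probability rho a protein's carriage of
  type t is copied from its carriage of type s, planting same-protein
  co-existence beyond independence;
* edge assortativity ``phi`` — a fraction phi of network edges is rewired
  to connect a type-s with a type-t carrier, planting cross-protein PTM
  interaction enrichment;
* disease bias ``gamma`` — disease label probability proportional to
  ``(k+1)^gamma``;
* GO skew — annotation rate of one leaf term multiplied for carriers of a
  chosen PTM type, planting GO enrichment.

All defaults are the neutral (null) condition: no planted effects, with
baseline carriage rates echoing the relative abundance of the major
modification types (phosphorylation most frequent). A seed fully
determines every output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .enrichment import GoDag
from .pin import InteractionNetwork
from .ptm_data import PTMRecord

logger = logging.getLogger(__name__)

#: per-type one-letter residue alphabets, for format realism only
RESIDUE_ALPHABETS = {
    "phosphorylation": "STY",
    "acetylation": "K",
    "ubiquitination": "K",
    "methylation": "RK",
    "glycosylation": "NST",
    "sumoylation": "K",
    "nitrosylation": "C",
}


@dataclass
class PTMTypeSpec:
    """Generative parameters for one PTM type."""

    name: str
    alpha: float = 0.1        # baseline carriage rate in (0, 1)
    beta: float = 0.0         # degree-bias exponent
    lam: float = 1.5          # mean sites per carrier (>= 1, truncated Poisson)
    subtypes: tuple[str, ...] = ()


def default_ptm_types() -> list[PTMTypeSpec]:
    """Neutral study-like mix, no planted structure.

    Carriage rates echo the relative abundance of the major types in the
    human data (phosphorylation most frequent, then ubiquitination and
    acetylation, glycosylation rarer); glycosylation is deliberately rare
    enough to fall below the default 1000-site abundance threshold at the
    default network size, exercising the filter the way low-frequency
    types were dropped in the original datasets.
    """
    return [
        PTMTypeSpec("phosphorylation", alpha=0.35, lam=4.0,
                    subtypes=("phosphorylation:S/T", "phosphorylation:Y")),
        PTMTypeSpec("acetylation", alpha=0.20, lam=3.0),
        PTMTypeSpec("ubiquitination", alpha=0.20, lam=3.0),
        PTMTypeSpec("glycosylation", alpha=0.08, lam=2.0,
                    subtypes=("glycosylation:N-linked", "glycosylation:O-linked")),
    ]


@dataclass
class SimulationConfig:
    seed: int = 0
    species: int = 9606
    n_proteins: int = 2000
    graph_model: str = "scale-free"     # scale-free | uniform-random | block
    attachment_m: int = 3
    edge_prob: float = 0.005
    block_sizes: tuple[int, ...] = (500, 500)
    block_probs: tuple[tuple[float, ...], ...] = ((0.02, 0.002), (0.002, 0.02))
    ptm_types: list[PTMTypeSpec] = field(default_factory=default_ptm_types)
    coupling: dict[tuple[str, str], float] = field(default_factory=dict)   # rho
    edge_assortativity: dict[tuple[str, str], float] = field(default_factory=dict)  # phi
    n_sources: int = 2
    duplicate_rate: float = 0.3
    disease_rate: float = 0.1
    disease_gamma: float = 0.0
    go_depth: int = 3
    go_branching: int = 3
    go_leaf_rate: float = 0.05
    go_skew: float = 1.0
    go_skew_type: str | None = None
    go_skew_leaf: str | None = None

    def __post_init__(self):
        for name, val in [("duplicate_rate", self.duplicate_rate),
                          ("disease_rate", self.disease_rate)]:
            if not 0 <= val <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for d, hi in [(self.coupling, 1.0), (self.edge_assortativity, 1.0)]:
            for k, v in d.items():
                if not 0 <= v < hi:
                    raise ValueError(f"coupling/assortativity {k} out of range: {v}")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, salt]))

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["coupling"] = {f"{a}|{b}": v for (a, b), v in self.coupling.items()}
        d["edge_assortativity"] = {
            f"{a}|{b}": v for (a, b), v in self.edge_assortativity.items()
        }
        return json.dumps(d, indent=2, default=list)


def _protein_id(i: int) -> str:
    return f"P{i:05d}"


def generate_network(cfg: SimulationConfig) -> InteractionNetwork:
    """Simple undirected graph per the configured model.

    Edge confidences are drawn Uniform(0.9, 1) so the default confidence
    filter keeps every edge; determinism follows from the config seed.
    """
    n = cfg.n_proteins
    rng = cfg.rng(1)
    nx_seed = int(rng.integers(2**31 - 1))
    if cfg.graph_model == "scale-free":
        if cfg.attachment_m >= n:
            raise ValueError("attachment m must be < n_proteins")
        g = nx.barabasi_albert_graph(n, cfg.attachment_m, seed=nx_seed)
    elif cfg.graph_model == "uniform-random":
        g = nx.gnp_random_graph(n, cfg.edge_prob, seed=nx_seed)
    elif cfg.graph_model == "block":
        if sum(cfg.block_sizes) != n:
            raise ValueError("block sizes must sum to n_proteins")
        g = nx.stochastic_block_model(
            list(cfg.block_sizes), [list(r) for r in cfg.block_probs], seed=nx_seed
        )
        g = nx.Graph(g)  # drop SBM block metadata wrapper
    else:
        raise ValueError(f"unknown graph model {cfg.graph_model!r}")
    g = nx.relabel_nodes(g, {i: _protein_id(i) for i in g.nodes})
    conf = rng.uniform(0.9, 1.0, size=g.number_of_edges())
    for (u, v), c in zip(g.edges, conf):
        g[u][v]["confidence"] = float(c)
    return InteractionNetwork(g, species=cfg.species, source_label="synthetic")


def _carriage_probs(degrees: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """P(carry) proportional to (k+1)^beta, scaled to mean alpha, capped at 1."""
    w = (degrees + 1.0) ** beta
    p = alpha * w * len(w) / w.sum()
    return np.minimum(p, 1.0)


def carrier_sets(net: InteractionNetwork, cfg: SimulationConfig) -> dict[str, set]:
    """Sample the per-type carrier sets (the ground truth behind the records)."""
    nodes = sorted(net.graph.nodes)
    degrees = np.array([net.graph.degree(p) for p in nodes], dtype=float)
    rng = cfg.rng(2)
    carriage: dict[str, np.ndarray] = {}
    for spec in cfg.ptm_types:
        p = _carriage_probs(degrees, spec.alpha, spec.beta)
        carriage[spec.name] = rng.random(len(nodes)) < p
    # coupling: with prob rho, type-t carriage is copied from type-s carriage
    for (s, t), rho in sorted(cfg.coupling.items()):
        if s not in carriage or t not in carriage:
            raise ValueError(f"coupling refers to unknown types {(s, t)}")
        copy_mask = rng.random(len(nodes)) < rho
        carriage[t] = np.where(copy_mask, carriage[s], carriage[t])
    if not any(m.any() for m in carriage.values()):
        logger.warning("no protein carries any PTM; empty dataset")
    return {t: {nodes[i] for i in np.flatnonzero(m)} for t, m in carriage.items()}


def assign_ptms(
    net: InteractionNetwork, cfg: SimulationConfig, carriers: dict[str, set] | None = None
) -> tuple[list[PTMRecord], dict[str, int]]:
    """Emit raw multi-source PTM records plus protein lengths.

    Per-carrier site counts are 1 + Poisson(lam - 1); site positions are
    sampled without replacement from 1..length (lengths ~ LogNormal,
    median ~450 residues); each record is emitted by one source and
    duplicated into a second source with probability ``duplicate_rate`` to
    exercise consolidation. Residues are drawn from a per-type alphabet.
    """
    if carriers is None:
        carriers = carrier_sets(net, cfg)
    nodes = sorted(net.graph.nodes)
    rng = cfg.rng(3)
    lengths = {
        p: max(50, int(round(ln))) for p, ln in
        zip(nodes, np.exp(rng.normal(np.log(450.0), 0.5, size=len(nodes))))
    }
    specs = {s.name: s for s in cfg.ptm_types}
    sources = [f"srcDB{i + 1}" for i in range(cfg.n_sources)]
    records: list[PTMRecord] = []
    for t in sorted(carriers):
        spec = specs.get(t, PTMTypeSpec(t))
        alphabet = RESIDUE_ALPHABETS.get(t, "ACDEFGHIKLMNPQRSTVWY")
        for prot in sorted(carriers[t]):
            n_sites = 1 + rng.poisson(max(spec.lam - 1.0, 0.0))
            n_sites = min(n_sites, lengths[prot])
            positions = rng.choice(lengths[prot], size=n_sites, replace=False) + 1
            for pos in sorted(int(x) for x in positions):
                residue = alphabet[int(rng.integers(len(alphabet)))]
                subtype = (
                    spec.subtypes[int(rng.integers(len(spec.subtypes)))]
                    if spec.subtypes else None
                )
                src = sources[int(rng.integers(len(sources)))]
                records.append(PTMRecord(
                    species=cfg.species, protein_id=prot, position=pos,
                    ptm_type=t, residue=residue, ptm_subtype=subtype,
                    sources=(src,), experimental=True,
                ))
                if cfg.n_sources > 1 and rng.random() < cfg.duplicate_rate:
                    others = [s for s in sources if s != src]
                    dup = others[int(rng.integers(len(others)))]
                    records.append(PTMRecord(
                        species=cfg.species, protein_id=prot, position=pos,
                        ptm_type=t, residue=residue, ptm_subtype=subtype,
                        sources=(dup,), experimental=True,
                    ))
    return records, lengths


def rewire_assortative(
    net: InteractionNetwork,
    labels: dict[str, set],
    type_a: str,
    type_b: str,
    phi: float,
    seed: int = 0,
) -> InteractionNetwork:
    """Replace a fraction phi of edges by random type_a--type_b carrier edges.

    The degree sequence is not preserved; the graph stays simple. Raises
    when either type has no carriers.
    """
    a_pool = sorted(labels.get(type_a, ()))
    b_pool = sorted(labels.get(type_b, ()))
    if not a_pool or not b_pool:
        raise ValueError("no carriers of one of the requested types")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    g = net.graph.copy()
    edges = sorted(g.edges)
    n_rewire = int(round(phi * len(edges)))
    chosen = rng.choice(len(edges), size=n_rewire, replace=False)
    for idx in chosen:
        u, v = edges[idx]
        conf = g[u][v]["confidence"]
        g.remove_edge(u, v)
        for _ in range(100):
            a = a_pool[int(rng.integers(len(a_pool)))]
            b = b_pool[int(rng.integers(len(b_pool)))]
            if a != b and not g.has_edge(a, b):
                g.add_edge(a, b, confidence=conf)
                break
        else:  # pathological pools: restore the original edge
            g.add_edge(u, v, confidence=conf)
    return InteractionNetwork(g, net.species, net.source_label)


def assign_disease(net: InteractionNetwork, cfg: SimulationConfig) -> set:
    """Disease labels with probability proportional to rate * (k+1)^gamma."""
    if cfg.disease_rate <= 0:
        return set()
    nodes = sorted(net.graph.nodes)
    degrees = np.array([net.graph.degree(p) for p in nodes], dtype=float)
    p = _carriage_probs(degrees, cfg.disease_rate, cfg.disease_gamma)
    rng = cfg.rng(5)
    return {nodes[i] for i in np.flatnonzero(rng.random(len(nodes)) < p)}


def generate_go(cfg: SimulationConfig, type_sets: dict[str, set] | None = None,
                proteins: list[str] | None = None) -> GoDag:
    """Balanced toy is_a DAG with leaf-level annotations.

    One root per namespace ("process" by default only); depth levels of
    ``go_branching`` children each. Every protein is annotated to each
    leaf independently at ``go_leaf_rate``; carriers of ``go_skew_type``
    get their rate multiplied by ``go_skew`` on ``go_skew_leaf`` (or on
    the first leaf), planting recoverable enrichment.
    """
    if cfg.go_depth < 1:
        raise ValueError("go_depth must be >= 1")
    if proteins is None:
        proteins = [_protein_id(i) for i in range(cfg.n_proteins)]
    terms: dict[str, dict] = {}
    parents: dict[str, frozenset] = {}
    root = "GO:ROOT0"
    terms[root] = {"name": "root", "namespace": "process"}
    level = [root]
    counter = 1
    for _ in range(cfg.go_depth):
        nxt = []
        for parent in level:
            for _ in range(cfg.go_branching):
                tid = f"GO:{counter:07d}"
                counter += 1
                terms[tid] = {"name": f"toy term {counter}", "namespace": "process"}
                parents[tid] = frozenset({parent})
                nxt.append(tid)
        level = nxt
    leaves = level
    skew_leaf = cfg.go_skew_leaf or leaves[0]
    skew_carriers = (type_sets or {}).get(cfg.go_skew_type or "", set())
    rng = cfg.rng(6)
    annotations: dict[str, set] = {}
    for prot in proteins:
        for leaf in leaves:
            rate = cfg.go_leaf_rate
            if leaf == skew_leaf and prot in skew_carriers:
                rate = min(1.0, rate * cfg.go_skew)
            if rng.random() < rate:
                annotations.setdefault(prot, set()).add(leaf)
    return GoDag(terms, parents, annotations)


# ---------------------------------------------------------------------------
# writers: exactly the dialects the ingest modules read

def write_ptm_tsv(records: list[PTMRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("taxid\tprotein_id\tposition\tresidue\tptm_type\tptm_subtype\t"
                 "source_db\texperimental\n")
        for r in records:
            fh.write(
                f"{r.species}\t{r.protein_id}\t{r.position}\t{r.residue}\t{r.ptm_type}\t"
                f"{r.ptm_subtype or ''}\t{';'.join(r.sources)}\t{int(r.experimental)}\n"
            )


def write_lengths_tsv(lengths: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tlength\n")
        for p in sorted(lengths):
            fh.write(f"{p}\t{lengths[p]}\n")


def write_string_tsv(net: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for u, v in sorted(map(lambda e: tuple(sorted(e)), net.graph.edges)):
            fh.write(f"{u}\t{v}\t{net.graph[u][v]['confidence']:.4f}\n")


def write_gaf(annotations: dict[str, set], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("!protein_id\tgo_id\n")
        for prot in sorted(annotations):
            for term in sorted(annotations[prot]):
                fh.write(f"{prot}\t{term}\n")


def write_obo(dag: GoDag, path: str | Path) -> None:
    long_ns = {"process": "biological_process", "function": "molecular_function",
               "component": "cellular_component"}
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: toy\n")
        for tid in sorted(dag.terms):
            meta = dag.terms[tid]
            fh.write(f"\n[Term]\nid: {tid}\nname: {meta['name']}\n")
            fh.write(f"namespace: {long_ns.get(meta['namespace'], meta['namespace'])}\n")
            for parent in sorted(dag.parents.get(tid, ())):
                fh.write(f"is_a: {parent} ! {dag.terms[parent]['name']}\n")


def write_disease_list(proteins: set, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in sorted(proteins):
            fh.write(p + "\n")


def write_all(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate every input and write it under ``outdir``. Returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net = generate_network(cfg)
    carriers = carrier_sets(net, cfg)
    for (a, b), phi in sorted(cfg.edge_assortativity.items()):
        if phi > 0:
            net = rewire_assortative(net, carriers, a, b, phi, seed=cfg.seed)
    records, lengths = assign_ptms(net, cfg, carriers)
    disease = assign_disease(net, cfg)
    dag = generate_go(cfg, carriers, proteins=sorted(net.graph.nodes))
    paths = {
        "ptm": outdir / "ptm_records.tsv",
        "lengths": outdir / "protein_lengths.tsv",
        "edges": outdir / "edges_string.tsv",
        "gaf": outdir / "annotations.gaf.tsv",
        "obo": outdir / "ontology.obo",
        "disease": outdir / "disease_proteins.txt",
        "config": outdir / "config.json",
    }
    write_ptm_tsv(records, paths["ptm"])
    write_lengths_tsv(lengths, paths["lengths"])
    write_string_tsv(net, paths["edges"])
    write_gaf(dag.annotations, paths["gaf"])
    write_obo(dag, paths["obo"])
    write_disease_list(disease, paths["disease"])
    paths["config"].write_text(cfg.to_json())
    return paths
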