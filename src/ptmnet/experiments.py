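"""Calibration and planted-effect recovery experiments.

These are the package's statistical validation runs: with every planted
effect switched off the significance machinery should call (almost)
nothing significant at its nominal FDR level, and each planted effect —
degree-biased PTM carriage, same-protein type coupling, edge
assortativity, degree-biased disease labels — should be recovered by
exactly the module that targets it. The functions return plain numbers so
they can back both the test suite and the reproducibility script.

All replicate seeds are spawned deterministically from one base seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import compare, cooccur, crosstalk, enrichment, pin, synthetic
from .ptm_data import TypeProteinSets

NULL_TYPES = {"phosphorylation": 0.30, "acetylation": 0.15,
              "ubiquitination": 0.15, "glycosylation": 0.08}


@dataclass
class RecoveryResult:
    n_success: int
    n_replicates: int
    extra: dict

    @property
    def rate(self) -> float:
        return self.n_success / self.n_replicates


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31 - 1)]


def _random_sets(rng: np.random.Generator, proteins: list[str],
                 rates: dict[str, float]) -> dict[str, set]:
    """Carrier sets drawn independently of topology (the null condition)."""
    out = {}
    for t, a in rates.items():
        mask = rng.random(len(proteins)) < a
        out[t] = {p for p, m in zip(proteins, mask) if m}
    return out


# ---------------------------------------------------------------------------
# null calibration (all planted effects off)

def null_compare_calibration(seed: int = 0, n: int = 2000,
                             n_replicates: int = 200) -> tuple[float, int]:
    """Fraction of FDR<0.05-significant property comparisons under the null.

    One scale-free network; per replicate, carrier sets are drawn
    independently of topology, every type x property is compared, and BH
    is applied per property within the replicate.
    """
    net = synthetic.generate_network(synthetic.SimulationConfig(seed=seed, n_proteins=n))
    props = pin.property_table(net)
    proteins = sorted(net.nodes)
    sig = total = 0
    for s in _child_seeds(seed + 1, n_replicates):
        rng = np.random.default_rng(s)
        sets = _random_sets(rng, proteins, NULL_TYPES)
        results = []
        for t, carriers in sorted(sets.items()):
            results.extend(compare.compare_type(props, carriers, ptm_type=t))
        compare.adjust_results(results)
        tested = [r for r in results if r.tested]
        total += len(tested)
        sig += sum(r.p_fdr < 0.05 for r in tested)
    return sig / total, total


def null_cooccur_calibration(seed: int = 0, n: int = 2000,
                             n_replicates: int = 200) -> tuple[float, int]:
    """Fraction of significant co-existence edges (FDR<0.01) under the null."""
    proteins = [f"P{i:05d}" for i in range(n)]
    sig = total = 0
    for s in _child_seeds(seed + 2, n_replicates):
        rng = np.random.default_rng(s)
        sets = _random_sets(rng, proteins, NULL_TYPES)
        tps = TypeProteinSets(9606, sets, "all")
        edges = cooccur.test_species(tps, universe=set(proteins))
        total += len(edges)
        sig += sum(e.significant for e in edges)
    return sig / total, total


def null_crosstalk_calibration(seed: int = 0, n: int = 1000, n_per_type: int = 50,
                               n_types: int = 3, n_replicates: int = 200) -> tuple[float, int]:
    """Fraction of significant type-pair interaction tests under label shuffling."""
    net = synthetic.generate_network(synthetic.SimulationConfig(seed=seed, n_proteins=n))
    proteins = sorted(net.nodes)
    names = [f"type{i}" for i in range(n_types)]
    sig = total = 0
    for s in _child_seeds(seed + 3, n_replicates):
        rng = np.random.default_rng(s)
        chosen = rng.choice(len(proteins), size=n_per_type * n_types, replace=False)
        sets = {t: {proteins[i] for i in chosen[j * n_per_type:(j + 1) * n_per_type]}
                for j, t in enumerate(names)}
        tps = TypeProteinSets(net.species, sets, "one-type-only")
        results = crosstalk.test_species(net, tps)
        total += len(results)
        sig += sum(r.significant for r in results)
    return sig / total, total


def null_disease_calibration(seed: int = 0, n: int = 2000,
                             n_replicates: int = 200) -> tuple[float, int]:
    """Fraction of significant quartile disease tests (FDR<0.01) under the null."""
    net = synthetic.generate_network(synthetic.SimulationConfig(seed=seed, n_proteins=n))
    props = pin.property_table(net)
    proteins = sorted(net.nodes)
    sig = total = 0
    for s in _child_seeds(seed + 4, n_replicates):
        rng = np.random.default_rng(s)
        sets = _random_sets(rng, proteins, NULL_TYPES)
        disease = {p for p in proteins if rng.random() < 0.1}
        df = enrichment.disease_tests(props, sets, disease)
        tested = df[df["tested"]]
        total += len(tested)
        sig += int((tested["p_fdr"] < 0.01).sum())
    return sig / total, total


# ---------------------------------------------------------------------------
# planted-effect recovery

def degree_bias_recovery(seed: int = 0, beta: float = 1.0, n: int = 2000,
                         n_carriers: int = 300, n_replicates: int = 100) -> RecoveryResult:
    """Recovery of a planted degree bias by the property comparison.

    Per replicate a fresh scale-free network is generated and exactly
    ``n_carriers`` proteins are labeled with probability proportional to
    (k+1)^beta. Success: the degree comparison reports the planted
    direction (higher for beta>0, lower for beta<0) at FDR < 0.01.
    """
    want = "higher" if beta > 0 else "lower"
    folds = []
    wins = 0
    for s in _child_seeds(seed + 5, n_replicates):
        net = synthetic.generate_network(synthetic.SimulationConfig(seed=s, n_proteins=n))
        proteins = sorted(net.nodes)
        k = np.array([net.graph.degree(p) for p in proteins], dtype=float)
        w = (k + 1.0) ** beta
        rng = np.random.default_rng(s)
        idx = rng.choice(len(proteins), size=n_carriers, replace=False, p=w / w.sum())
        carriers = {proteins[i] for i in idx}
        props = pin.property_table(net, properties=("degree",))
        [res] = compare.compare_type(props, carriers, properties=("degree",))
        compare.adjust_results([res])
        if res.direction == want and res.p_fdr < 0.01:
            wins += 1
        folds.append(res.log2_fold)
    return RecoveryResult(wins, n_replicates, {"mean_log2_fold": float(np.mean(folds))})


def coupling_recovery(seed: int = 0, rho: float = 0.5, n: int = 2000,
                      n_replicates: int = 100) -> RecoveryResult:
    """Recovery of planted same-protein coupling by the co-existence test.

    Two types with baseline rates 0.15 are coupled at ``rho``; success is
    an FDR<0.01 significant co-existence edge for that pair. The closed
    -form Jaccard expected under independence,
    ``a*b / (a + b - a*b)``, is reported alongside the observed mean.
    """
    a = b = 0.15
    others = {"phosphorylation": 0.3}
    wins = 0
    jaccards = []
    proteins = [f"P{i:05d}" for i in range(n)]
    for s in _child_seeds(seed + 6, n_replicates):
        rng = np.random.default_rng(s)
        x_s = rng.random(n) < a
        x_t = rng.random(n) < b
        copy = rng.random(n) < rho
        x_t = np.where(copy, x_s, x_t)
        sets = {"typeS": {p for p, m in zip(proteins, x_s) if m},
                "typeT": {p for p, m in zip(proteins, x_t) if m}}
        sets.update(_random_sets(rng, proteins, others))
        tps = TypeProteinSets(9606, sets, "all")
        edges = cooccur.test_species(tps, universe=set(proteins))
        edge = next(e for e in edges if {e.type_a, e.type_b} == {"typeS", "typeT"})
        wins += int(edge.significant)
        jaccards.append(edge.jaccard)
    independence = a * b / (a + b - a * b)
    return RecoveryResult(wins, n_replicates, {
        "mean_jaccard": float(np.mean(jaccards)),
        "independence_jaccard": independence,
    })


def assortativity_recovery(seed: int = 0, phi: float = 0.3, n: int = 1000,
                           n_per_type: int = 50, n_replicates: int = 100) -> RecoveryResult:
    """Recovery of planted edge assortativity by the cross-protein test.

    Disjoint one-type-only sets of ``n_per_type`` proteins are labeled a
    and b; a fraction ``phi`` of edges is rewired to connect an a-carrier
    with a b-carrier. Success: the (a, b) pair is FDR<0.01 significant.
    """
    wins = 0
    for s in _child_seeds(seed + 7, n_replicates):
        net = synthetic.generate_network(synthetic.SimulationConfig(seed=s, n_proteins=n))
        proteins = sorted(net.nodes)
        rng = np.random.default_rng(s)
        chosen = rng.choice(len(proteins), size=2 * n_per_type, replace=False)
        sets = {"typeA": {proteins[i] for i in chosen[:n_per_type]},
                "typeB": {proteins[i] for i in chosen[n_per_type:]}}
        net = synthetic.rewire_assortative(net, sets, "typeA", "typeB", phi, seed=s)
        tps = TypeProteinSets(net.species, sets, "one-type-only")
        results = crosstalk.test_species(net, tps)
        hit = next(r for r in results if {r.type_a, r.type_b} == {"typeA", "typeB"})
        wins += int(hit.significant)
    return RecoveryResult(wins, n_replicates, {})


def disease_bias_recovery(seed: int = 0, gamma: float = 2.0, n: int = 2000,
                          n_replicates: int = 100) -> RecoveryResult:
    """Recovery of degree-biased disease labels by the top-quartile test."""
    net = synthetic.generate_network(synthetic.SimulationConfig(seed=seed, n_proteins=n))
    props = pin.property_table(net, properties=("degree",))
    proteins = sorted(net.nodes)
    k = np.array([net.graph.degree(p) for p in proteins], dtype=float)
    w = (k + 1.0) ** gamma
    p_label = np.minimum(0.1 * w * len(w) / w.sum(), 1.0)
    wins = 0
    for s in _child_seeds(seed + 8, n_replicates):
        rng = np.random.default_rng(s)
        disease = {p for p, pr in zip(proteins, p_label) if rng.random() < pr}
        carriers = {p for p in proteins if rng.random() < 0.3}
        res = enrichment.disease_overlap_test(props, carriers, disease, "degree", "top")
        wins += int(res.tested and res.p_raw < 0.01)
    return RecoveryResult(wins, n_replicates, {})


def go_skew_recovery(seed: int = 0, skew: float = 10.0, n: int = 2000) -> dict:
    """Single-run recovery of a planted GO annotation skew.

    Returns the rank of the skewed leaf (or an ancestor) in the focal
    type's enrichment list under the classic method.
    """
    cfg = synthetic.SimulationConfig(seed=seed, n_proteins=n, go_skew=skew,
                                     go_skew_type="phosphorylation")
    net = synthetic.generate_network(cfg)
    carriers = synthetic.carrier_sets(net, cfg)
    dag = synthetic.generate_go(cfg, carriers, proteins=sorted(net.nodes))
    dag = enrichment.annotation_closure(dag)
    background = set(dag.annotations)
    study = carriers["phosphorylation"] & background
    results = enrichment.go_enrich(study, background, dag, method="classic")
    has_child: set = set()
    for ps in dag.parents.values():
        has_child |= ps
    leaves = sorted(set(dag.terms) - has_child)
    target = cfg.go_skew_leaf or leaves[0]
    labels = [r.label for r in results]
    rank = labels.index(target) if target in labels else math.inf
    top_p = results[0].p_fdr if results else math.nan
    return {"rank_of_skewed_leaf": rank, "top_p_fdr": float(top_p),
            "significant": bool(results and results[0].p_fdr < 0.01)}
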