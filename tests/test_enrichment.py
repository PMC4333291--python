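"""GO annotation closure, classic/elim enrichment and disease quartile tests."""

import math

import numpy as np
import pandas as pd
import pytest

import oracles
from ptmnet import enrichment
from ptmnet.enrichment import GoDag, annotation_closure, go_enrich


def chain_dag(annotations=None):
    terms = {t: {"name": t, "namespace": "process"} for t in ("leaf", "mid", "root")}
    parents = {"leaf": frozenset({"mid"}), "mid": frozenset({"root"})}
    return GoDag(terms, parents, annotations or {})


def four_term_dag():
    """root <- parent <- child, plus an independent leaf 'other' under root.

    The parent's only signal comes from the child's proteins: classic calls
    both significant, elim eliminates the child's genes and clears the parent.
    """
    terms = {t: {"name": t, "namespace": "process"}
             for t in ("root", "parent", "child", "other")}
    parents = {"parent": frozenset({"root"}), "child": frozenset({"parent"}),
               "other": frozenset({"root"})}
    ann = {f"g{i}": {"child"} for i in range(10)}
    ann |= {f"h{i}": {"other"} for i in range(30)}
    return GoDag(terms, parents, ann)


class TestClosure:
    def test_chain_closure(self):
        dag = chain_dag({"p1": {"leaf"}})
        closed = annotation_closure(dag)
        assert closed.annotations["p1"] == {"leaf", "mid", "root"}

    def test_idempotent(self):
        closed = annotation_closure(chain_dag({"p1": {"leaf"}}))
        again = annotation_closure(closed)
        assert again.annotations == closed.annotations

    def test_diamond_both_branches(self):
        terms = {t: {"name": t, "namespace": "process"} for t in "RABL"}
        parents = {"A": frozenset({"R"}), "B": frozenset({"R"}),
                   "L": frozenset({"A", "B"})}
        dag = GoDag(terms, parents, {"p": {"L"}})
        closed = annotation_closure(dag)
        assert closed.annotations["p"] == {"L", "A", "B", "R"}

    def test_cycle_detected(self):
        terms = {t: {"name": t, "namespace": "process"} for t in "XY"}
        parents = {"X": frozenset({"Y"}), "Y": frozenset({"X"})}
        with pytest.raises(ValueError, match="cycle"):
            annotation_closure(GoDag(terms, parents, {}))

    def test_unknown_annotated_term_rejected(self):
        dag = chain_dag({"p1": {"nope"}})
        with pytest.raises(ValueError):
            annotation_closure(dag)

    def test_closure_monotone_background_counts(self):
        dag = annotation_closure(four_term_dag())
        res = go_enrich({"g0"}, set(dag.annotations), dag)
        counts = {r.label: r.bg_count for r in res}
        assert counts["parent"] >= counts["child"]
        assert counts["root"] >= counts["parent"]


class TestGoEnrich:
    def test_maximal_enrichment_matches_tail_oracle(self):
        # N=100, K=10, n=10, k=10
        terms = {"T": {"name": "T", "namespace": "process"},
                 "root": {"name": "root", "namespace": "process"}}
        parents = {"T": frozenset({"root"})}
        ann = {f"t{i}": {"T"} for i in range(10)}
        ann |= {f"u{i}": {"root"} for i in range(90)}
        dag = GoDag(terms, parents, ann)
        study = {f"t{i}" for i in range(10)}
        res = {r.label: r for r in go_enrich(study, set(ann), dag)}
        assert res["T"].p_raw == pytest.approx(oracles.hypergeom_tail(10, 100, 10, 10), rel=1e-9)
        assert res["T"].study_count == 10 and res["T"].bg_count == 10

    def test_parent_significant_classic_not_elim(self):
        dag = four_term_dag()
        study = {f"g{i}" for i in range(10)}
        background = set(dag.annotations)
        classic = {r.label: r for r in go_enrich(study, background, dag, "classic")}
        elim = {r.label: r for r in go_enrich(study, background, dag, "elim", alpha=0.01)}
        assert classic["parent"].p_raw < 0.01
        assert classic["child"].p_raw < 0.01
        assert elim["child"].p_raw < 0.01
        assert elim["parent"].p_raw == 1.0          # study genes eliminated
        assert elim["parent"].study_count == 0

    def test_elim_with_nonpositive_alpha_equals_classic(self):
        dag = four_term_dag()
        study = {f"g{i}" for i in range(10)} | {"h0", "h1"}
        background = set(dag.annotations)
        classic = go_enrich(study, background, dag, "classic")
        elim0 = go_enrich(study, background, dag, "elim", alpha=0.0)
        c = {r.label: (r.p_raw, r.study_count, r.bg_count) for r in classic}
        e = {r.label: (r.p_raw, r.study_count, r.bg_count) for r in elim0}
        assert c == e

    def test_null_study_calibrated(self):
        rng = np.random.default_rng(17)
        terms = {f"T{j}": {"name": f"T{j}", "namespace": "process"} for j in range(40)}
        parents = {}
        ann = {}
        proteins = [f"p{i}" for i in range(400)]
        for prot in proteins:
            ann[prot] = {f"T{j}" for j in range(40) if rng.random() < 0.08} or {"T0"}
        dag = GoDag(terms, parents, ann)
        frac = []
        for _ in range(40):
            study = set(rng.choice(proteins, 60, replace=False))
            res = go_enrich(study, set(proteins), dag)
            frac.append(np.mean([r.p_raw < 0.05 for r in res]))
        assert np.mean(frac) <= 0.08

    def test_empty_study_raises(self):
        with pytest.raises(ValueError):
            go_enrich(set(), {"p"}, chain_dag({"p": {"leaf"}}))

    def test_study_not_subset_raises(self):
        with pytest.raises(ValueError):
            go_enrich({"q"}, {"p"}, chain_dag({"p": {"leaf"}}))


class TestTopTermsMatrix:
    @staticmethod
    def _res(label, pfdr):
        return enrichment.EnrichmentResult(label, 5, 10, 10, 100, p_raw=pfdr, p_fdr=pfdr)

    def test_identical_columns_merge_first(self):
        by_type = {
            "phos": [self._res("T1", 1e-6), self._res("T2", 1e-4)],
            "acet": [self._res("T1", 1e-6), self._res("T2", 1e-4)],
            "glyc": [self._res("T3", 1e-8)],
        }
        mat = enrichment.top_terms_matrix(by_type)
        order = mat.attrs["col_order"]
        assert abs(order.index("phos") - order.index("acet")) == 1

    def test_single_type_single_column(self):
        mat = enrichment.top_terms_matrix({"phos": [self._res("T1", 1e-4)]})
        assert list(mat.columns) == ["phos"] and list(mat.index) == ["T1"]

    def test_top_k_limits_rows(self):
        results = [self._res(f"T{i}", 1e-6 * (i + 1)) for i in range(8)]
        mat = enrichment.top_terms_matrix({"phos": results}, k=5)
        assert len(mat) == 5
        assert set(mat.index) == {f"T{i}" for i in range(5)}  # smallest p first

    def test_no_significant_terms_empty(self):
        mat = enrichment.top_terms_matrix({"phos": [self._res("T1", 0.5)]})
        assert mat.empty

    def test_hand_computed_merge_order_3x3(self):
        # column vectors: x=(5,0), y=(5,1), z=(0,9): d(x,y)=1 < d(y,z), d(x,z)
        by_type = {
            "x": [self._res("A", 10**-5.0)],
            "y": [self._res("A", 10**-5.0), self._res("B", 0.1 ** 1)],
            "z": [self._res("C", 10**-9.0)],
        }
        by_type["y"][1] = self._res("B", 10**-1.0)
        mat = enrichment.top_terms_matrix(by_type, sig_level=0.5)
        order = mat.attrs["col_order"]
        assert abs(order.index("x") - order.index("y")) == 1


class TestDiseaseOverlap:
    @staticmethod
    def _props(n=200, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({"degree": rng.integers(1, 60, size=n).astype(float)},
                          index=pd.Index([f"P{i}" for i in range(n)], name="protein_id"))
        return df

    def test_disease_equals_top_quartile_minimal_p(self):
        props = self._props()
        ptm = set(props.index)
        cut = np.quantile(props["degree"], 0.75)
        disease = set(props.index[props["degree"] >= cut])
        res = enrichment.disease_overlap_test(props, ptm, disease, "degree", "top")
        assert res.p_raw < 1e-20
        assert res.study_count == res.study_size

    def test_q_one_degenerates_to_whole_set(self):
        props = self._props()
        ptm = {f"P{i}" for i in range(0, 200, 2)}
        disease = {f"P{i}" for i in range(0, 200, 3)}
        res = enrichment.disease_overlap_test(props, ptm, disease, "degree", "top", q=1.0)
        assert res.study_size == len(ptm)

    def test_tail_sets_disjoint_for_q_leq_half(self):
        props = self._props(seed=3)
        ptm = set(props.index)
        top = enrichment.disease_overlap_test(props, ptm, set(), "degree", "top", q=0.25)
        bot = enrichment.disease_overlap_test(props, ptm, set(), "degree", "bottom", q=0.25)
        assert top.study_size + bot.study_size <= len(ptm) + \
            np.sum(props["degree"] == np.quantile(props["degree"], 0.25))
        # explicit membership check
        cut_hi = np.quantile(props["degree"], 0.75)
        cut_lo = np.quantile(props["degree"], 0.25)
        assert cut_lo < cut_hi  # tails cannot overlap on this draw

    def test_empty_tail_flagged_untested(self):
        props = self._props()
        res = enrichment.disease_overlap_test(props, set(), {"P1"}, "degree", "top")
        assert not res.tested

    def test_grid_has_one_fdr_family(self):
        props = self._props(seed=5)
        sets = {"phos": {f"P{i}" for i in range(100)},
                "acet": {f"P{i}" for i in range(50, 150)}}
        df = enrichment.disease_tests(props, sets, {f"P{i}" for i in range(0, 200, 4)},
                                      properties=("degree",))
        tested = df[df["tested"]]
        ours = tested["p_fdr"].to_numpy()
        assert np.allclose(ours, oracles.bh_stepup(tested["p_raw"].to_numpy()), atol=1e-12)
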