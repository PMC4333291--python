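"""Consolidation, abundance/outlier filtering and protein-set construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import rec
from ptmnet import ptm_data
from ptmnet.ptm_data import PTMRecord, consolidate, abundance_filter, build_type_sets, outlier_filter


class TestConsolidate:
    def test_same_site_two_sources_collapses_to_one_record(self):
        ds = consolidate([rec("P1", 5, "phosphorylation", source="dbA"),
                          rec("P1", 5, "phosphorylation", source="dbB")])
        assert len(ds) == 1
        assert set(ds.records[0].sources) == {"dbA", "dbB"}

    def test_distinct_positions_stay_distinct(self):
        ds = consolidate([rec("P1", 5, "phosphorylation"), rec("P1", 9, "phosphorylation")])
        assert len(ds) == 2

    def test_type_is_part_of_the_key(self):
        # six raw rows spanning 4 distinct (species, protein, position, type) keys
        rows = [
            rec("P1", 5, "phosphorylation"),
            rec("P1", 5, "glycosylation"),
            rec("P1", 5, "phosphorylation", source="db2"),
            rec("P2", 5, "phosphorylation"),
            rec("P1", 5, "phosphorylation", species=10090),
            rec("P1", 5, "glycosylation", source="db2"),
        ]
        expected = len({r.key for r in rows})
        assert len(consolidate(rows)) == expected == 4

    def test_non_experimental_dropped(self):
        ds = consolidate([rec("P1", 5, "phosphorylation", experimental=False)])
        assert len(ds) == 0

    def test_invalid_position_rejected_at_construction(self):
        with pytest.raises(ValueError):
            PTMRecord(species=1, protein_id="P1", position=0, ptm_type="phosphorylation")
        with pytest.raises(ValueError):
            PTMRecord(species=1, protein_id="P1", position=3, ptm_type="")

    def test_malformed_rows_skipped_not_crash(self, tmp_path):
        p = tmp_path / "ptm.tsv"
        p.write_text(
            "taxid\tprotein_id\tposition\tresidue\tptm_type\tptm_subtype\tsource_db\texperimental\n"
            "# a comment line\n"
            "9606\tP1\t5\tS\tphosphorylation\t\tdbA\t1\n"
            "9606\tP2\tnot_a_number\tS\tphosphorylation\t\tdbA\t1\n"
            "9606\tP3\t-4\tS\tphosphorylation\t\tdbA\t1\n"
        )
        records = ptm_data.load_ptm_tsv(p)
        assert [r.protein_id for r in records] == ["P1"]

    def test_id_mapping_applied_and_unmapped_dropped(self, tmp_path):
        p = tmp_path / "ptm.tsv"
        p.write_text(
            "taxid\tprotein_id\tposition\tresidue\tptm_type\tptm_subtype\tsource_db\texperimental\n"
            "9606\tOLD1\t5\tS\tphosphorylation\t\tdbA\t1\n"
            "9606\tNOPE\t6\tS\tphosphorylation\t\tdbA\t1\n"
        )
        records = ptm_data.load_ptm_tsv(p, id_map={"OLD1": "NEW1"})
        assert [r.protein_id for r in records] == ["NEW1"]

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.tuples(st.sampled_from("PQRS"), st.integers(1, 5),
                              st.sampled_from(["phosphorylation", "acetylation"]),
                              st.sampled_from(["dbA", "dbB"])), max_size=20))
    def test_consolidation_idempotent(self, rows):
        records = [rec(p, pos, t, source=s) for p, pos, t, s in rows]
        once = consolidate(records)
        twice = consolidate(once.records)
        assert sorted(r.key for r in once.records) == sorted(r.key for r in twice.records)
        assert all(
            set(a.sources) == set(b.sources)
            for a, b in zip(sorted(once.records, key=lambda r: r.key),
                            sorted(twice.records, key=lambda r: r.key))
        )


class TestAbundanceFilter:
    @staticmethod
    def _bulk(ptm_type, n, species=9606, start=0):
        return [rec(f"P{start + i}", 1, ptm_type, species=species) for i in range(n)]

    def test_type_with_exactly_1000_sites_dropped(self):
        ds = consolidate(self._bulk("amidation", 1000) + self._bulk("phosphorylation", 1001, start=2000))
        res = abundance_filter(ds)
        assert res.retained_types == ["phosphorylation"]

    def test_species_with_exactly_1000_sites_kept(self):
        ds = consolidate(self._bulk("phosphorylation", 1001, species=9606)
                         + self._bulk("phosphorylation", 1000, species=10090, start=3000))
        res = abundance_filter(ds)
        assert res.retained_species == [9606, 10090]

    def test_boundary_1001_type_and_species_retained(self):
        ds = consolidate(self._bulk("phosphorylation", 1001))
        res = abundance_filter(ds)
        assert res.retained_types == ["phosphorylation"]
        assert res.retained_species == [9606]
        assert len(res.dataset) == 1001

    def test_zero_thresholds_retain_everything(self):
        ds = consolidate([rec("P1", 1, "phosphorylation"), rec("P2", 1, "amidation")])
        res = abundance_filter(ds, type_min=0, species_min=0)
        assert len(res.dataset) == 2

    def test_empty_dataset_warns_and_returns_empty(self):
        res = abundance_filter(consolidate([]))
        assert res.retained_types == [] and res.retained_species == []


class TestOutlierFilter:
    def test_site_count_outlier_removed_mean_plus_3sd(self):
        # 99 proteins with 1 site, one with 200: mean=2.99, sd~19.9, cutoff~62.7
        records = [rec(f"P{i}", 1, "phosphorylation") for i in range(99)]
        records += [rec("BIG", pos, "phosphorylation") for pos in range(1, 201)]
        ds = consolidate(records, {f"P{i}": 100 for i in range(99)} | {"BIG": 300})
        counts = np.array([1] * 99 + [200], dtype=float)
        assert counts.mean() + 3 * counts.std(ddof=1) < 200
        out = outlier_filter(ds)
        kept = {r.protein_id for r in out.records}
        assert "BIG" not in kept and len(kept) == 99

    def test_identical_lengths_no_length_removal(self):
        records = [rec(f"P{i}", 1, "phosphorylation") for i in range(100)]
        ds = consolidate(records, {f"P{i}": 500 for i in range(100)})
        out = outlier_filter(ds)
        assert len({r.protein_id for r in out.records}) == 100

    def test_length_percentile_matches_sorting_oracle(self):
        rng = np.random.default_rng(42)
        lengths = {f"P{i}": int(l) for i, l in enumerate(rng.integers(50, 2000, size=200))}
        records = [rec(p, 1, "phosphorylation") for p in lengths]
        ds = consolidate(records, lengths)
        out = outlier_filter(ds)
        kept = {r.protein_id for r in out.records}
        vals = np.array(sorted(lengths.values()), dtype=float)
        lo, hi = np.percentile(vals, [1, 99])  # same convention, independent path
        expected_removed = {p for p, l in lengths.items() if l < lo or l > hi}
        assert kept == set(lengths) - expected_removed
        assert expected_removed  # the draw does produce tail proteins

    def test_fewer_than_three_proteins_is_noop(self):
        ds = consolidate([rec("P1", i, "phosphorylation") for i in range(1, 100)]
                         + [rec("P2", 1, "phosphorylation")],
                         {"P1": 100, "P2": 100})
        out = outlier_filter(ds)
        assert len(out) == len(ds)


class TestTypeSets:
    def test_modes(self):
        records = [rec("ONLYP", 1, "phosphorylation"),
                   rec("BOTH", 1, "phosphorylation"), rec("BOTH", 2, "acetylation")]
        ds = consolidate(records)
        allm = build_type_sets(ds, "all")[9606]
        assert allm.assignment["phosphorylation"] == {"ONLYP", "BOTH"}
        assert allm.assignment["acetylation"] == {"BOTH"}
        single = build_type_sets(ds, "one-type-only")[9606]
        assert single.assignment["phosphorylation"] == {"ONLYP"}
        assert "BOTH" not in single.proteins()

    def test_subtype_mode(self):
        records = [rec("P1", 1, "phosphorylation", ptm_subtype="phosphorylation:S/T"),
                   rec("P1", 2, "phosphorylation", ptm_subtype="phosphorylation:Y")]
        sets = build_type_sets(consolidate(records), "subtype")[9606]
        assert sets.assignment == {"phosphorylation:S/T": {"P1"}, "phosphorylation:Y": {"P1"}}

    def test_unknown_mode_raises(self):
        with pytest.raises(ValueError):
            build_type_sets(consolidate([]), "nope")

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.tuples(st.sampled_from("PQRSTU"), st.integers(1, 3),
                              st.sampled_from(["phosphorylation", "acetylation", "methylation"])),
                    min_size=1, max_size=25))
    def test_one_type_only_subset_of_all_and_disjoint(self, rows):
        ds = consolidate([rec(p, pos, t) for p, pos, t in rows])
        allm = build_type_sets(ds, "all").get(9606)
        single = build_type_sets(ds, "one-type-only").get(9606)
        if single is None:
            return
        for t, s in single.assignment.items():
            assert s <= allm.assignment[t]
        types = single.types()
        for i, a in enumerate(types):
            for b in types[i + 1:]:
                assert not (single.assignment[a] & single.assignment[b])
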