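import numpy as np
import pytest

from mtqscreen import core_data
from mtqscreen.core_data import (
    ActivityRecord,
    Dataset,
    ExperimentalCondition,
    SplitSpec,
    assign_labels,
    curate,
    load_activity_table,
    load_dataset,
    save_dataset,
    split_random,
)
from mtqscreen.errors import ConfigurationError, DataError


COND = ExperimentalCondition(bt="MNK-1", me="IC50", at="B")


def rec(cid="c1", cond=COND, value=None, relation="=", label=None, row=0):
    return ActivityRecord(
        compound_id=cid, condition=cond, value_nM=value, relation=relation,
        label=label, row_index=row,
    )


class TestConditionOntology:
    def test_equality_and_hashing_is_elementwise(self):
        a = ExperimentalCondition(bt="MNK-1", me="IC50", at="B")
        assert a == COND and hash(a) == hash(COND)
        assert a != ExperimentalCondition(bt="MNK-2", me="IC50", at="B")

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(bt="", me="IC50", at="B"),
            dict(bt="MNK-1", me="EC50", at="B"),
            dict(bt="MNK-1", me="IC50", at="X"),
        ],
    )
    def test_invalid_elements_rejected(self, kwargs):
        with pytest.raises(DataError):
            ExperimentalCondition(**kwargs)

    def test_record_needs_label_or_value(self):
        with pytest.raises(DataError):
            ActivityRecord(compound_id="c", condition=COND)


class TestLoading:
    def test_row_count_and_order_preserved(self, tmp_path):
        p = tmp_path / "act.csv"
        p.write_text(
            "compound_id,bt,me,at,value_nM\n"
            "a,MNK-1,IC50,B,50\nb,MNK-2,Ki,B,500\nc,MNK-1,Kd,F,<20\n"
        )
        ds = load_activity_table(p)
        assert len(ds) == 3
        assert [r.compound_id for r in ds] == ["a", "b", "c"]
        assert ds.records[2].relation == "<"
        assert ds.records[2].value_nM == 20.0

    def test_tab_delimited_autodetected(self, tmp_path):
        p = tmp_path / "act.tsv"
        p.write_text("compound_id\tbt\tme\tat\tvalue_nM\na\tMNK-1\tIC50\tB\t50\n")
        assert len(load_activity_table(p)) == 1

    def test_unknown_measure_token_rejected_with_line(self, tmp_path):
        p = tmp_path / "act.csv"
        p.write_text("compound_id,bt,me,at,value_nM\na,MNK-1,EC50,B,50\n")
        with pytest.raises(DataError, match="line 2"):
            load_activity_table(p)

    def test_missing_required_column_is_config_error(self, tmp_path):
        p = tmp_path / "act.csv"
        p.write_text("compound_id,me,at,value_nM\na,IC50,B,50\n")
        with pytest.raises(ConfigurationError, match="bt"):
            load_activity_table(p)

    def test_precomputed_labels_pass_through(self, tmp_path):
        p = tmp_path / "act.csv"
        p.write_text("compound_id,bt,me,at,label\na,MNK-1,IC50,B,1\nb,MNK-1,IC50,B,-1\n")
        ds = load_activity_table(p)
        assert [r.label for r in ds] == [1, -1]
        assert all(r.value_nM is None for r in ds)

    def test_dialect_renames_columns(self, tmp_path):
        p = tmp_path / "act.csv"
        p.write_text("mol,target,measure,assay,act\na,MNK-1,IC50,B,50\n")
        ds = load_activity_table(
            p,
            dialect={"compound_id": "mol", "bt": "target", "me": "measure",
                     "at": "assay", "value": "act"},
        )
        assert ds.records[0].value_nM == 50.0

    def test_roundtrip_bundle(self, tmp_path):
        p = tmp_path / "act.csv"
        p.write_text(
            "compound_id,bt,me,at,value_nM\na,MNK-1,IC50,B,50\nb,MNK-2,Ki,F,<10\n"
        )
        ds = load_activity_table(p)
        save_dataset(ds, tmp_path / "bundle", sidecar={"note": "x"})
        back, meta = load_dataset(tmp_path / "bundle")
        assert meta["note"] == "x"
        assert [r.compound_id for r in back] == [r.compound_id for r in ds]
        assert [r.condition for r in back] == [r.condition for r in ds]
        assert [r.value_nM for r in back] == [r.value_nM for r in ds]
        assert [r.relation for r in back] == [r.relation for r in ds]


class TestLabelAssignment:
    CUTS = {"IC50": 100.0, "Ki": 300.0, "Kd": 300.0}

    @pytest.mark.parametrize(
        "me,value,relation,expected",
        [
            ("IC50", 50, "=", 1),     # potent, below the 100 nM IC50 cutoff
            ("Ki", 200, "=", 1),      # below the 300 nM Ki cutoff
            ("IC50", 150, "=", -1),   # above cutoff -> inactive
            ("IC50", 100, "=", 1),    # boundary is inclusive for actives
            ("IC50", 80, "<", 1),     # '<80' conclusively potent
            ("Kd", 500, ">", -1),     # '>500' conclusively inactive
        ],
    )
    def test_cutoff_rule(self, me, value, relation, expected):
        ds = Dataset([rec(value=value, relation=relation,
                          cond=ExperimentalCondition(bt="MNK-1", me=me, at="B"))])
        labeled, excluded = assign_labels(ds, self.CUTS)
        assert not excluded
        assert labeled.records[0].label == expected

    @pytest.mark.parametrize("value,relation", [(500, "<"), (50, ">")])
    def test_ambiguous_censored_records_excluded(self, value, relation):
        ds = Dataset([rec(value=value, relation=relation)])
        labeled, excluded = assign_labels(ds, self.CUTS)
        assert len(labeled) == 0 and len(excluded) == 1
        assert excluded[0]["relation"] == relation

    def test_existing_labels_untouched(self):
        ds = Dataset([rec(value=5000, label=1)])
        labeled, _ = assign_labels(ds, self.CUTS)
        assert labeled.records[0].label == 1

    def test_uncovered_measure_is_config_error(self):
        ds = Dataset([rec(value=50)])
        with pytest.raises(ConfigurationError):
            assign_labels(ds, {"Ki": 300.0})


class TestCuration:
    def test_exact_duplicates_collapse_to_one(self):
        ds = Dataset([rec(label=1, row=0), rec(label=1, row=1)])
        out, report = curate(ds)
        assert len(out) == 1 and out.records[0].row_index == 0
        assert len(report.duplicates_collapsed) == 1

    def test_conflicting_duplicates_removed_entirely(self):
        ds = Dataset([rec(label=1), rec(label=-1), rec(cid="c2", label=1, row=2)])
        out, report = curate(ds)
        assert [r.compound_id for r in out] == ["c2"]
        assert len(report.conflicts_removed) == 1

    def test_same_compound_different_condition_kept(self):
        other = ExperimentalCondition(bt="MNK-2", me="IC50", at="B")
        ds = Dataset([rec(label=1), rec(cond=other, label=-1, row=1)])
        out, _ = curate(ds)
        assert len(out) == 2

    def test_idempotent(self):
        ds = Dataset([rec(label=1), rec(label=1, row=1), rec(cid="z", label=-1, row=2)])
        once, _ = curate(ds)
        twice, rep = curate(once)
        assert [r.compound_id for r in twice] == [r.compound_id for r in once]
        assert not rep.duplicates_collapsed and not rep.conflicts_removed


class TestSplitting:
    @staticmethod
    def _dataset(n):
        return Dataset([rec(cid=f"c{i}", label=1 if i % 3 else -1, row=i)
                        for i in range(n)])

    def test_reference_sizes_1892(self):
        # 30% external then 20% test reproduces the 1059/265/568 partition
        sub, test, ext = split_random(
            self._dataset(1892), SplitSpec(seed=7, external_fraction=0.30,
                                           test_fraction=0.20)
        )
        assert (len(sub), len(test), len(ext)) == (1059, 265, 568)

    def test_tiny_rounding_ties_up(self):
        sub, test, ext = split_random(
            self._dataset(10), SplitSpec(seed=0, external_fraction=0.5,
                                         test_fraction=0.2)
        )
        assert (len(sub), len(test), len(ext)) == (4, 1, 5)

    def test_same_seed_identical_partition(self):
        spec = SplitSpec(seed=11)
        a = split_random(self._dataset(100), spec)
        b = split_random(self._dataset(100), spec)
        for x, y in zip(a, b):
            assert [r.compound_id for r in x] == [r.compound_id for r in y]

    def test_partition_exhaustive_and_disjoint(self):
        ds = self._dataset(97)
        parts = split_random(ds, SplitSpec(seed=3))
        ids = [r.compound_id for p in parts for r in p]
        assert sorted(ids) == sorted(r.compound_id for r in ds)
        assert len(set(ids)) == len(ids)

    def test_empty_set_is_error(self):
        with pytest.raises(DataError):
            split_random(self._dataset(3), SplitSpec(seed=0, external_fraction=0.01,
                                                     test_fraction=0.01))

    def test_fraction_bounds_validated(self):
        with pytest.raises(ConfigurationError):
            SplitSpec(seed=0, external_fraction=1.2)
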