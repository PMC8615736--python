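import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mtqscreen import boxjenkins, validation
from mtqscreen.boxjenkins import DescriptorBlock
from mtqscreen.core_data import ActivityRecord, Dataset, ExperimentalCondition
from mtqscreen.errors import DataError
from mtqscreen.validation import (
    ConfusionCounts,
    applicability_domain,
    auroc,
    conditionwise,
    confusion,
    metrics,
    random_accuracy,
    yc_randomization,
)

# Printed confusion counts and derived statistics of the published two-isoform
# models (linear original, linear refined, random-forest, gradient-boosting),
# per evaluation set.  Accrnd is only printed for the two linear models.
PRINTED = [
    # (TP, TN, FP, FN, Acc, F1, MCC, Accrnd)
    (308, 674, 20, 57, 92.73, 88.89, 0.838, 55.91),
    (88, 154, 11, 12, 91.32, 88.44, 0.815, 53.10),
    (147, 362, 20, 39, 89.61, 83.29, 0.760, 57.11),
    (310, 677, 17, 55, 93.20, 89.59, 0.848, 55.94),
    (89, 158, 7, 11, 93.20, 90.82, 0.855, 53.38),
    (148, 367, 15, 38, 90.67, 84.81, 0.785, 57.35),
    (314, 653, 41, 51, 91.31, 87.22, None, None),
    (81, 152, 13, 19, 87.92, 83.50, 0.741, None),
    (148, 361, 21, 38, 89.61, 83.38, 0.760, None),
    (318, 660, 34, 47, 92.35, 88.70, None, None),
    (87, 158, 7, 13, 92.45, 89.69, 0.838, None),
    (150, 365, 17, 36, 90.67, 84.98, 0.785, None),
]


def _tol(printed: float) -> float:
    """Agreement to the printed precision (reference tool truncates)."""
    decimals = len(str(printed).split(".")[1])
    return 10.0 ** (-decimals)


class TestConfusion:
    def test_all_correct(self):
        c = confusion([1, -1, 1], [1, -1, 1])
        assert (c.TP, c.TN, c.FP, c.FN) == (2, 1, 0, 0)

    def test_inversion_swaps_counts(self):
        y = [1, 1, -1, -1, -1]
        p = [1, -1, -1, 1, -1]
        c = confusion(y, p)
        ci = confusion(y, [-v for v in p])
        assert (ci.TP, ci.FN) == (c.FN, c.TP)
        assert (ci.TN, ci.FP) == (c.FP, c.TN)

    def test_empty_is_error(self):
        with pytest.raises(DataError):
            confusion([], [])

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            confusion([1], [1, -1])


class TestMetrics:
    @pytest.mark.parametrize("tp,tn,fp,fn,acc,f1,mcc,accrnd", PRINTED)
    def test_reproduces_printed_tables(self, tp, tn, fp, fn, acc, f1, mcc, accrnd):
        rep = metrics(ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn))
        assert abs(rep.Acc - acc) < _tol(acc)
        assert abs(rep.F1 - f1) < _tol(f1)
        if mcc is not None:
            assert abs(rep.MCC - mcc) < _tol(mcc)
        if accrnd is not None:
            assert abs(rep.Accrnd - accrnd) < _tol(accrnd)

    def test_perfect_classifier(self):
        rep = metrics(ConfusionCounts(TP=5, TN=5, FP=0, FN=0))
        assert rep.Acc == 100.0 and rep.MCC == 1.0 and rep.F1 == 100.0

    def test_mcc_zero_denominator_convention(self):
        rep = metrics(ConfusionCounts(TP=0, TN=0, FP=0, FN=3))
        assert rep.MCC == 0.0

    def test_symmetric_counts_accrnd_50(self):
        assert random_accuracy(ConfusionCounts(TP=4, TN=4, FP=4, FN=4)) == 50.0

    @given(
        tp=st.integers(0, 200), tn=st.integers(0, 200),
        fp=st.integers(0, 200), fn=st.integers(0, 200),
    )
    @settings(max_examples=200, derandomize=True)
    def test_accrnd_invariant_to_class_swap(self, tp, tn, fp, fn):
        # swapping TP<->TN together with FP<->FN relabels the classes
        if tp + tn + fp + fn == 0:
            return
        a = random_accuracy(ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn))
        b = random_accuracy(ConfusionCounts(TP=tn, TN=tp, FP=fn, FN=fp))
        assert a == pytest.approx(b)

    @given(
        tp=st.integers(0, 100), tn=st.integers(0, 100),
        fp=st.integers(0, 100), fn=st.integers(0, 100),
    )
    @settings(max_examples=200, derandomize=True)
    def test_metric_ranges(self, tp, tn, fp, fn):
        if tp + tn + fp + fn == 0:
            return
        rep = metrics(ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn))
        for v in (rep.Sn, rep.Sp, rep.Acc, rep.F1, rep.Accrnd):
            assert 0.0 <= v <= 100.0
        assert -1.0 <= rep.MCC <= 1.0


class TestAuroc:
    def test_perfect_separation(self):
        auc, _ = auroc([0.9, 0.8, 0.1, 0.2], [1, 1, -1, -1])
        assert auc == 1.0

    def test_concordant_pair_fraction(self):
        # actives {0.9, 0.4} vs inactives {0.5, 0.1}: 3 of 4 pairs concordant
        auc, _ = auroc([0.9, 0.4, 0.5, 0.1], [1, 1, -1, -1])
        assert auc == pytest.approx(0.75)

    def test_all_ties_half(self):
        auc, _ = auroc([1.0, 1.0, 1.0, 1.0], [1, 1, -1, -1])
        assert auc == pytest.approx(0.5)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=60)
        y = np.where(rng.random(60) < 0.4, 1, -1)
        a1, _ = auroc(s, y)
        a2, _ = auroc(np.exp(s) + 3, y)
        a3, _ = auroc(np.tanh(s / 2), y)
        assert a1 == pytest.approx(a2) == pytest.approx(a3)

    def test_single_class_is_error(self):
        with pytest.raises(DataError):
            auroc([0.1, 0.2], [1, 1])


def _synth_modeling(seed, effect):
    from mtqscreen import synthetic

    spec = synthetic.SynthSpec(n_compounds=400, n_noise=10, effect_size=effect,
                               seed=seed)
    ds, block, truth = synthetic.generate(spec)
    rows = np.arange(len(ds))
    sub = rows[:280]
    return ds, block, truth, rows, sub


class TestYcRandomization:
    def test_planted_signal_collapses_to_majority_rate(self):
        ds, block, truth, rows, sub = _synth_modeling(seed=21, effect=3.0)
        feats = [f"{c}__me" for c in truth["informative_columns"]]
        # the genuine model for comparison
        table = boxjenkins.fit_averages(block, ds, rows)
        modified = boxjenkins.transform(block, ds, table, fallback_global=True)
        from mtqscreen import lda_engine

        model = lda_engine.fit(modified.take(sub).select(feats), ds.labels()[sub])
        pred = lda_engine.classify(model, modified.take(sub).select(feats))
        true_acc = 100 * np.mean(pred == ds.labels()[sub])

        yc = yc_randomization(block, ds, feats, rows, sub, n_runs=12, seed=5)
        y_sub = ds.labels()[sub]
        majority = 100 * max((y_sub == 1).mean(), (y_sub == -1).mean())
        assert abs(yc.accuracy_r - majority) < 5.0
        assert yc.accuracy_r < true_acc - 10.0
        assert yc.lambda_r > 0.9

    def test_no_signal_lambda_matches_unpermuted(self):
        ds, block, truth, rows, sub = _synth_modeling(seed=22, effect=0.0)
        feats = [f"{c}__me" for c in truth["informative_columns"]]
        table = boxjenkins.fit_averages(block, ds, rows)
        modified = boxjenkins.transform(block, ds, table, fallback_global=True)
        from mtqscreen import lda_engine

        model = lda_engine.fit(modified.take(sub).select(feats), ds.labels()[sub])
        yc = yc_randomization(block, ds, feats, rows, sub, n_runs=10, seed=6)
        assert abs(yc.lambda_r - model.wilks_lambda) < 0.05

    def test_single_run_reproducible(self):
        ds, block, truth, rows, sub = _synth_modeling(seed=23, effect=2.0)
        feats = [f"{c}__bt" for c in truth["informative_columns"]]
        a = yc_randomization(block, ds, feats, rows, sub, n_runs=1, seed=9)
        b = yc_randomization(block, ds, feats, rows, sub, n_runs=1, seed=9)
        assert a.lambda_r == b.lambda_r and a.accuracy_r == b.accuracy_r


class TestConditionwise:
    C1 = ExperimentalCondition(bt="MNK-1", me="IC50", at="B")
    C2 = ExperimentalCondition(bt="MNK-2", me="Ki", at="F")

    def _dataset(self):
        recs = [
            ActivityRecord(compound_id=f"c{i}", condition=c, label=l, row_index=i)
            for i, (c, l) in enumerate(
                [(self.C1, 1), (self.C1, -1), (self.C2, 1), (self.C2, 1), (self.C2, -1)]
            )
        ]
        return Dataset(recs)

    def test_fully_correct_and_fully_wrong(self):
        ds = self._dataset()
        pred = [1, -1, -1, -1, 1]  # C1 all correct, C2 all wrong
        df = conditionwise(pred, ds)
        assert df.accuracy_pct.tolist() == [100.0, 0.0]
        assert df.n_instances.tolist() == [2, 3]

    def test_single_instance_condition_reported(self):
        c3 = ExperimentalCondition(bt="MNK-1", me="Kd", at="B")
        ds = Dataset(
            self._dataset().records
            + [ActivityRecord(compound_id="x", condition=c3, label=1, row_index=5)]
        )
        df = conditionwise([1, -1, 1, 1, -1, -1], ds)
        row = df[df.me == "Kd"].iloc[0]
        assert row.n_instances == 1 and row.accuracy_pct == 0.0

    def test_recomposes_overall_accuracy(self, synth_data):
        ds, _, _ = synth_data
        rng = np.random.default_rng(3)
        pred = np.where(rng.random(len(ds)) < 0.5, 1, -1)
        df = conditionwise(pred, ds)
        overall = np.sum(df.n_instances * df.accuracy_pct) / np.sum(df.n_instances)
        assert overall == pytest.approx(100 * np.mean(pred == ds.labels()))
        assert len(df) == 7  # the seven default conditions

    def test_seven_conditions_in_fixture(self, synth_data):
        ds, _, _ = synth_data
        assert len(ds.conditions()) == 7


class TestApplicabilityDomain:
    STATS = {
        "a": {"mean": 0.0, "sd": 1.0},
        "b": {"mean": 10.0, "sd": 2.0},
        "c": {"mean": -5.0, "sd": 0.5},
    }

    def test_training_mean_vector_inside(self):
        res = applicability_domain(self.STATS, {"a": 0.0, "b": 10.0, "c": -5.0})
        assert res.inside and all(z == 0.0 for z in res.z_scores.values())

    def test_all_z_above_three_is_outlier(self):
        res = applicability_domain(self.STATS, {"a": 5.0, "b": 20.0, "c": -2.5})
        assert not res.inside
        assert min(res.z_scores.values()) > 3

    def test_borderline_decided_by_mean_plus_ksd(self):
        query = {"a": 0.1, "b": 18.0, "c": -5.05}  # z = (0.1, 4.0, 0.1)
        res = applicability_domain(self.STATS, query)
        z = np.array([0.1, 4.0, 0.1])
        expected = z.mean() + 1.28 * z.std(ddof=1) <= 3.0
        assert res.inside == expected

    def test_missing_descriptor_is_error(self):
        with pytest.raises(DataError):
            applicability_domain(self.STATS, {"a": 0.0, "b": 10.0})

    def test_matrix_flags_agree_with_scalar_rule(self):
        rng = np.random.default_rng(4)
        names = list(self.STATS)
        X = rng.normal(0, 4, size=(40, 3)) + np.array([0.0, 10.0, -5.0])
        block = DescriptorBlock(column_names=names, values=X)
        flags = validation.ad_flags_matrix(self.STATS, block)
        for i in range(40):
            scalar = applicability_domain(
                self.STATS, dict(zip(names, X[i]))
            ).inside
            assert flags[i] == scalar
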