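"""Outcome measures, folds, aggregation and cohort summaries.

The AUC implementation (threshold sweep + trapezoid) is checked against a
brute-force pairwise Mann-Whitney oracle written independently here.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cystfuse as cf


def pairwise_auc_oracle(scores, labels):
    """Brute force: fraction of (pos, neg) pairs correctly ordered, ties 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == "MCN"]
    neg = [s for s, l in zip(scores, labels) if l == "SCN"]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_predictions(self):
        labels = ["MCN"] * 3 + ["SCN"] * 2
        c = cf.confusion(labels, labels)
        assert (c.true_mcn, c.false_scn, c.true_scn, c.false_mcn) == (3, 0, 2, 0)

    def test_all_predicted_positive(self):
        labels = ["MCN"] * 3 + ["SCN"] * 2
        c = cf.confusion(["MCN"] * 5, labels)
        assert (c.true_mcn, c.false_scn, c.true_scn, c.false_mcn) == (3, 0, 0, 2)

    def test_mixed_enumerated_example(self):
        preds = ["MCN", "SCN", "MCN", "SCN", "SCN"]
        labels = ["MCN", "MCN", "SCN", "SCN", "MCN"]
        c = cf.confusion(preds, labels)
        assert (c.true_mcn, c.false_scn, c.true_scn, c.false_mcn) == (1, 2, 1, 1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(cf.ValidationError):
            cf.confusion(["MCN"], ["MCN", "SCN"])


class TestSensSpecAcc:
    def test_printed_formula_example(self):
        sens, spec, acc = cf.sens_spec_acc(cf.ConfusionCounts(29, 7, 25, 8))
        assert sens == pytest.approx(29 / 36)
        assert spec == pytest.approx(25 / 33)
        assert acc == pytest.approx(54 / 69)

    def test_perfect_confusion(self):
        assert cf.sens_spec_acc(cf.ConfusionCounts(5, 0, 3, 0)) == (1.0, 1.0, 1.0)

    def test_zero_denominator_is_missing_not_error(self):
        sens, spec, acc = cf.sens_spec_acc(cf.ConfusionCounts(0, 0, 3, 1))
        assert sens is None and spec is not None and acc is not None

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        tm=st.integers(0, 50), fs=st.integers(0, 50),
        ts=st.integers(0, 50), fm=st.integers(0, 50),
    )
    def test_accuracy_decomposition_identity(self, tm, fs, ts, fm):
        """acc = (sens * n_mcn + spec * n_scn) / n whenever all are defined."""
        n_mcn, n_scn = tm + fs, ts + fm
        if n_mcn == 0 or n_scn == 0:
            return
        sens, spec, acc = cf.sens_spec_acc(cf.ConfusionCounts(tm, fs, ts, fm))
        assert acc == pytest.approx((sens * n_mcn + spec * n_scn) / (n_mcn + n_scn))


class TestRocAuc:
    def test_perfect_separation(self):
        assert cf.roc_auc([0.9, 0.8, 0.2, 0.1], ["MCN", "MCN", "SCN", "SCN"]) == 1.0

    def test_constant_scores(self):
        assert cf.roc_auc([0.5] * 6, ["MCN"] * 3 + ["SCN"] * 3) == pytest.approx(0.5)

    def test_three_of_four_pairs(self):
        auc = cf.roc_auc([0.9, 0.4, 0.5, 0.1], ["MCN", "MCN", "SCN", "SCN"])
        assert auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(cf.ValidationError):
            cf.roc_auc([0.5, 0.6], ["MCN", "MCN"])

    def test_matches_pairwise_oracle_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(4, 50))
            labels = ["MCN" if v else "SCN" for v in rng.integers(0, 2, n)]
            if len(set(labels)) < 2:
                labels[0], labels[1] = "MCN", "SCN"
            # coarse grid of scores forces plenty of ties
            scores = rng.integers(0, 5, n) / 4.0
            auc = cf.roc_auc(scores, labels)
            assert abs(auc - pairwise_auc_oracle(scores, labels)) < 1e-12


class TestMakeFolds:
    def test_clinical_cohort_split(self):
        patients = [f"p{i}" for i in range(69)]
        labels = ["SCN"] * 33 + ["MCN"] * 36
        folds = cf.make_folds(patients, labels, k=4, seed=0)
        sizes = sorted(len(folds.fold_patients(f)) for f in range(4))
        assert sizes == [17, 17, 17, 18]
        scn_counts = sorted(
            sum(1 for p in folds.fold_patients(f) if labels[patients.index(p)] == "SCN")
            for f in range(4)
        )
        mcn_counts = sorted(
            sum(1 for p in folds.fold_patients(f) if labels[patients.index(p)] == "MCN")
            for f in range(4)
        )
        assert scn_counts == [8, 8, 8, 9]
        assert mcn_counts == [9, 9, 9, 9]

    def test_partition_properties(self):
        patients = [f"p{i}" for i in range(23)]
        labels = (["SCN"] * 11) + (["MCN"] * 12)
        folds = cf.make_folds(patients, labels, k=3, seed=5)
        all_assigned = [p for f in range(3) for p in folds.fold_patients(f)]
        assert sorted(all_assigned) == sorted(patients)
        assert len(set(all_assigned)) == len(patients)

    def test_deterministic(self):
        patients = [f"p{i}" for i in range(20)]
        labels = ["SCN", "MCN"] * 10
        a = cf.make_folds(patients, labels, k=4, seed=9)
        b = cf.make_folds(patients, labels, k=4, seed=9)
        assert a.assignment == b.assignment

    @pytest.mark.parametrize("k", [2, 3, 4, 5])
    def test_stratification_within_one_patient(self, k):
        rng = np.random.default_rng(k)
        n_scn, n_mcn = int(rng.integers(k, 30)), int(rng.integers(k, 30))
        patients = [f"p{i}" for i in range(n_scn + n_mcn)]
        labels = ["SCN"] * n_scn + ["MCN"] * n_mcn
        folds = cf.make_folds(patients, labels, k=k, seed=1)
        for f in range(k):
            members = folds.fold_patients(f)
            for cls, n_cls in (("SCN", n_scn), ("MCN", n_mcn)):
                got = sum(1 for p in members if labels[patients.index(p)] == cls)
                assert abs(got - n_cls / k) <= 1

    def test_small_class_rejected(self):
        with pytest.raises(cf.ValidationError):
            cf.make_folds(["a", "b", "c"], ["SCN", "SCN", "MCN"], k=2)
        with pytest.raises(cf.ValidationError):
            cf.make_folds(["a", "b"], ["SCN", "MCN"], k=1)


class TestAggregateFolds:
    def test_mean_of_folds(self):
        report = cf.aggregate_folds(
            [{"accuracy": v} for v in (0.8, 0.9, 0.7, 0.8)]
        )
        agg = report.aggregate()
        assert agg.loc["accuracy", "mean"] == pytest.approx(0.80)
        assert agg.loc["accuracy", "min"] == pytest.approx(0.7)
        assert agg.loc["accuracy", "max"] == pytest.approx(0.9)

    def test_single_fold(self):
        agg = cf.aggregate_folds([{"auc": 0.75}]).aggregate()
        assert agg.loc["auc", "sd"] == 0.0
        assert agg.loc["auc", "min"] == agg.loc["auc", "max"] == 0.75

    def test_fold_order_invariance(self):
        rows = [{"auc": v} for v in (0.6, 0.9, 0.7)]
        a = cf.aggregate_folds(rows).aggregate()
        b = cf.aggregate_folds(rows[::-1]).aggregate()
        pd.testing.assert_frame_equal(a, b)

    def test_missing_values_excluded(self):
        agg = cf.aggregate_folds(
            [{"auc": 0.8}, {"auc": None}, {"auc": 0.6}]
        ).aggregate()
        assert agg.loc["auc", "mean"] == pytest.approx(0.7)

    def test_summary_renders_mean_sd_range(self):
        text = cf.aggregate_folds([{"auc": 0.8}, {"auc": 0.9}]).summary()
        assert "±" in text and "[" in text


class TestCohortSummary:
    def _table(self):
        rows = []
        for _ in range(9):
            rows.append(dict(label="SCN", sex="M", age=55.0, tumor_size=2.8))
        for _ in range(24):
            rows.append(dict(label="SCN", sex="F", age=52.0, tumor_size=2.7))
        for _ in range(8):
            rows.append(dict(label="MCN", sex="M", age=49.0, tumor_size=3.1))
        for _ in range(28):
            rows.append(dict(label="MCN", sex="F", age=51.0, tumor_size=3.0))
        return pd.DataFrame(rows)

    def test_male_to_female_ratios(self):
        summary = cf.cohort_summary(self._table())
        assert summary.per_class.loc["SCN", "male_to_female"] == 0.38
        assert summary.per_class.loc["MCN", "male_to_female"] == 0.29
        assert summary.per_class.loc["SCN", "n"] == 33
        assert summary.per_class.loc["MCN", "n"] == 36

    def test_equal_counts_give_ratio_one(self):
        df = pd.DataFrame(
            dict(label=["SCN"] * 4 + ["MCN"] * 4, sex=["M", "M", "F", "F"] * 2)
        )
        summary = cf.cohort_summary(df)
        assert summary.per_class.loc["SCN", "male_to_female"] == 1.00

    def test_tests_are_flagged_defaults(self):
        summary = cf.cohort_summary(self._table())
        tests = set(summary.tests["test"])
        assert any("Welch" in t for t in tests)
        assert any("chi-square" in t for t in tests)
        assert any("Mann-Whitney" in t for t in tests)
        assert "not prescribed" in summary.summary()

    def test_missing_label_column_rejected(self):
        with pytest.raises(cf.ValidationError):
            cf.cohort_summary(pd.DataFrame({"sex": ["M"]}))
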