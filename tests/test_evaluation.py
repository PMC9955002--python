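"""Rebalancing, folds, metrics and ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn import metrics as skm

from seiztype import (
    anova_oneway,
    confusion,
    cross_validated_report,
    metrics,
    random_undersample,
    stratified_kfold,
)
from seiztype.evaluation import _gorodkin_rk
from seiztype.exceptions import InvalidArgumentError


def imbalanced_table(counts={"TCSZ": 83, "CPSZ": 114, "EGSZ": 282}, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for label, count in counts.items():
        for i in range(count):
            rows.append({"channel_id": f"{label}-{i}", "label": label,
                         "f1": rng.normal(), "f2": rng.normal()})
    return pd.DataFrame(rows)


class TestRandomUndersample:
    def test_published_counts_reduce_to_minority(self):
        table = imbalanced_table()
        balanced = random_undersample(table, seed=0)
        assert balanced["label"].value_counts().to_dict() == {
            "TCSZ": 83, "CPSZ": 83, "EGSZ": 83,
        }

    def test_already_balanced_is_identity(self):
        table = imbalanced_table({"TCSZ": 10, "CPSZ": 10, "EGSZ": 10})
        balanced = random_undersample(table, seed=1)
        assert sorted(balanced["channel_id"]) == sorted(table["channel_id"])

    def test_deterministic_under_seed(self):
        table = imbalanced_table()
        a = random_undersample(table, seed=7)["channel_id"].tolist()
        b = random_undersample(table, seed=7)["channel_id"].tolist()
        assert a == b

    def test_single_class_rejected(self):
        with pytest.raises(InvalidArgumentError):
            random_undersample(imbalanced_table({"TCSZ": 5}), seed=0)


class TestStratifiedKFold:
    def test_balanced_249_rows_split_evenly(self):
        labels = np.repeat(["TCSZ", "CPSZ", "EGSZ"], 83)
        plan = stratified_kfold(labels, k=10, seed=0)
        sizes = sorted(len(f) for f in plan.folds)
        assert set(sizes) <= {24, 25}
        for fold in plan.folds:
            counts = pd.Series(labels[fold]).value_counts()
            assert set(counts) <= {8, 9}

    def test_folds_disjoint_and_exhaustive(self):
        labels = np.repeat(["a", "b"], 25)
        plan = stratified_kfold(labels, k=5, seed=3)
        joined = np.sort(np.concatenate(plan.folds))
        assert np.array_equal(joined, np.arange(50))

    def test_k_one_rejected(self):
        with pytest.raises(InvalidArgumentError):
            stratified_kfold(np.repeat(["a", "b"], 10), k=1)

    def test_small_class_named_in_error(self):
        labels = np.array(["a"] * 20 + ["b"] * 3)
        with pytest.raises(InvalidArgumentError, match="b"):
            stratified_kfold(labels, k=10)


class TestConfusionAndMetrics:
    def test_perfect_predictions_are_diagonal(self):
        y = np.repeat(["TCSZ", "CPSZ", "EGSZ"], 10)
        counts = confusion(y, y)
        assert np.all(counts.matrix == np.diag([10, 10, 10]))
        report = metrics(counts)
        for value in report.macro.values():
            assert value == pytest.approx(1.0)

    def test_hand_worked_binary_counts(self):
        y_true = ["p"] * 50 + ["n"] * 50
        y_pred = ["p"] * 50 + ["p"] * 10 + ["n"] * 40
        counts = confusion(y_true, y_pred)
        c = counts.per_class["p"]
        assert (c["TP"], c["TN"], c["FP"], c["FN"]) == (50, 40, 10, 0)
        row = metrics(counts).per_class.loc["p"]
        assert row["SN"] == pytest.approx(1.0)
        assert row["SP"] == pytest.approx(0.8)
        assert row["PR"] == pytest.approx(0.8333, abs=5e-5)
        assert row["F1"] == pytest.approx(0.9091, abs=5e-5)
        assert row["MCC"] == pytest.approx(0.8165, abs=5e-5)

    def test_all_wrong_binary_gives_mcc_minus_one(self):
        y_true = ["a", "a", "b", "b"]
        y_pred = ["b", "b", "a", "a"]
        report = metrics(confusion(y_true, y_pred))
        assert report.per_class["MCC"].tolist() == pytest.approx([-1.0, -1.0])

    def test_label_swap_flips_binary_mcc_sign(self, rng):
        y_true = rng.choice(["a", "b"], 100)
        y_pred = rng.choice(["a", "b"], 100)
        mcc = metrics(confusion(y_true, y_pred)).per_class.loc["a", "MCC"]
        swap = {"a": "b", "b": "a"}
        swapped = metrics(
            confusion([swap[t] for t in y_true], y_pred)
        ).per_class.loc["a", "MCC"]
        assert mcc == pytest.approx(-swapped)

    def test_matches_sklearn_on_random_confusions(self, rng):
        """Per-class one-vs-rest metrics equal an independent implementation."""
        for _ in range(100):
            y_true = rng.choice(["x", "y", "z"], 60)
            y_pred = rng.choice(["x", "y", "z"], 60)
            report = metrics(confusion(y_true, y_pred))
            for label in "xyz":
                t = (np.asarray(y_true) == label).astype(int)
                p = (np.asarray(y_pred) == label).astype(int)
                row = report.per_class.loc[label]
                assert row["SN"] == pytest.approx(
                    skm.recall_score(t, p, zero_division=0), abs=1e-12
                )
                assert row["PR"] == pytest.approx(
                    skm.precision_score(t, p, zero_division=0), abs=1e-12
                )
                assert row["F1"] == pytest.approx(
                    skm.f1_score(t, p, zero_division=0), abs=1e-12
                )
                if len(set(t)) > 1 and len(set(p)) > 1:
                    assert row["MCC"] == pytest.approx(
                        skm.matthews_corrcoef(t, p), abs=1e-12
                    )

    def test_rk_generalization_matches_sklearn_multiclass_mcc(self, rng):
        y_true = rng.choice(["x", "y", "z"], 90)
        y_pred = rng.choice(["x", "y", "z"], 90)
        counts = confusion(y_true, y_pred)
        report = metrics(counts, multiclass_mcc="rk")
        assert report.mcc_multiclass_rk == pytest.approx(
            skm.matthews_corrcoef(y_true, y_pred), abs=1e-12
        )
        assert _gorodkin_rk(np.diag([5, 5, 5])) == pytest.approx(1.0)

    def test_zero_denominator_scores_zero_with_flag(self):
        counts = confusion(["a", "a", "b"], ["a", "a", "a"])
        report = metrics(counts)
        assert report.per_class.loc["b", "SN"] == 0.0
        assert any("zero-denominator" in f for f in report.flags)


class TestCrossValidatedReport:
    def test_deterministic_under_seed(self):
        table = imbalanced_table({"TCSZ": 20, "CPSZ": 20, "EGSZ": 20})
        a, fa = cross_validated_report(table, k=5, seed=9)
        b, fb = cross_validated_report(table, k=5, seed=9)
        assert np.array_equal(a.counts.matrix, b.counts.matrix)
        assert fa == fb

    def test_pooled_accuracy_equals_trace_over_n(self):
        table = imbalanced_table({"TCSZ": 20, "CPSZ": 20, "EGSZ": 20})
        report, _ = cross_validated_report(table, k=5, seed=1)
        trace_over_n = np.trace(report.counts.matrix) / report.counts.n
        # macro one-vs-rest accuracy differs in general; trace/n is the
        # pooled multiclass accuracy
        assert 0.0 <= trace_over_n <= 1.0
        assert report.counts.n == 60


class TestAnova:
    def test_hand_worked_three_groups(self):
        values = np.array([1, 2, 3, 2, 3, 4, 3, 4, 5], dtype=float)
        groups = np.repeat(["g1", "g2", "g3"], 3)
        f_stat, p = anova_oneway(values, groups)
        assert f_stat == pytest.approx(3.0)
        assert p == pytest.approx(1 - sps.f.cdf(3.0, 2, 6), abs=1e-12)

    def test_degenerate_identical_values_rejected(self):
        with pytest.raises(InvalidArgumentError):
            anova_oneway(np.ones(9), np.repeat(["a", "b", "c"], 3))

    def test_tiny_group_rejected(self):
        with pytest.raises(InvalidArgumentError):
            anova_oneway([1.0, 2.0, 3.0], ["a", "a", "b"])

    def test_type_i_error_rate_near_alpha(self):
        rng = np.random.default_rng(0)
        rejections = 0
        trials = 1000
        for _ in range(trials):
            values = rng.standard_normal(40)
            groups = np.repeat(["a", "b"], 20)
            _, p = anova_oneway(values, groups)
            rejections += p < 0.05
        assert rejections / trials == pytest.approx(0.05, abs=0.02)
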