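"""Metrics, cross-validation schemes and the Friedman/Dunn comparison."""

import numpy as np
import pandas as pd
import pytest

from evohdtree.evaluation import (
    ConfusionMatrix,
    accuracy,
    confusion,
    cross_validate,
    f1_score,
    friedman_compare,
    loocv,
    reports_to_table,
    roc_auc,
)
from evohdtree.io import LabeledDataset
from evohdtree.learners import MajorityLearner


class _ThresholdLearner:
    """Deterministic stub: predict 1 iff feature 0 > 0."""

    def fit(self, X, y, metabolite_names, seed=0):
        class _F:
            def predict(self, X):
                return (np.asarray(X)[:, 0] > 0).astype(int)

            def predict_score(self, X):
                return np.asarray(X)[:, 0]

        return _F()


class TestConfusion:
    def test_hand_example(self):
        cm = confusion([1, 1, 0, 0], [1, 0, 0, 0])
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (1, 1, 0, 2)

    def test_perfect(self):
        cm = confusion([1, 0, 1], [1, 0, 1])
        assert cm.fp == cm.fn == 0

    def test_all_negative_predictions(self):
        cm = confusion([1, 0], [0, 0])
        assert cm.tp == 0 and cm.fp == 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, fp=0, fn=0, tn=0)


class TestScalarMetrics:
    def test_f1_hand_example(self):
        assert f1_score(ConfusionMatrix(3, 1, 1, 5)) == pytest.approx(0.75)

    def test_f1_zero_without_true_positives(self):
        assert f1_score(ConfusionMatrix(0, 2, 3, 5)) == 0.0

    def test_f1_perfect(self):
        assert f1_score(ConfusionMatrix(4, 0, 0, 4)) == 1.0

    def test_accuracy(self):
        assert accuracy(ConfusionMatrix(3, 1, 1, 5)) == pytest.approx(0.8)
        with pytest.raises(ValueError):
            accuracy(ConfusionMatrix(0, 0, 0, 0))


class TestRocAuc:
    def test_perfect_and_reversed(self):
        y = [1, 1, 0, 0]
        assert roc_auc(y, [0.9, 0.8, 0.2, 0.1])[0] == 1.0
        assert roc_auc(y, [0.1, 0.2, 0.8, 0.9])[0] == 0.0

    def test_all_tied_scores_half(self):
        auc, _ = roc_auc([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5])
        assert auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1], [0.2, 0.3])

    def test_roc_points_span_unit_square(self):
        _, pts = roc_auc([1, 0, 1, 0, 1], [0.9, 0.8, 0.7, 0.3, 0.2])
        assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)
        fpr, tpr = zip(*pts)
        assert list(fpr) == sorted(fpr) and list(tpr) == sorted(tpr)


def _dataset(n_pos=6, n_neg=6, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_pos + n_neg, 3))
    y = np.array([1] * n_pos + [0] * n_neg)
    X[y == 1, 0] += 3.0
    return LabeledDataset(X, y, ["A", "B", "C"])


class TestCrossValidation:
    def test_pooled_metrics_with_deterministic_learner(self):
        d = _dataset(seed=1)
        rep = cross_validate(d, _ThresholdLearner(), k=3, n_runs=2, seed=1)
        # the stub ignores training data, so pooled predictions are exact
        pred = (d.values[:, 0] > 0).astype(int)
        cm = confusion(d.y, pred)
        assert rep.acc == pytest.approx(accuracy(cm))
        assert rep.f1 == pytest.approx(f1_score(cm))
        assert rep.acc_sd == pytest.approx(0.0)
        assert rep.n_runs == 2

    def test_fold_count_reduced_for_small_minority(self):
        d = _dataset(n_pos=2, n_neg=8, seed=2)
        rep = cross_validate(d, _ThresholdLearner(), k=5, seed=0)
        assert any("reduced" in n for n in rep.notes)
        assert rep.scheme.startswith("2-fold")

    def test_k_bounds(self):
        d = _dataset()
        with pytest.raises(ValueError):
            cross_validate(d, _ThresholdLearner(), k=1)
        with pytest.raises(ValueError):
            cross_validate(d, _ThresholdLearner(), k=99)

    def test_loocv_pools_every_sample_once(self):
        d = _dataset(seed=3)
        rep = loocv(d, _ThresholdLearner(), seed=3)
        assert rep.scheme == "LOOCV x1"
        pred = (d.values[:, 0] > 0).astype(int)
        assert rep.acc == pytest.approx(accuracy(confusion(d.y, pred)))

    def test_loocv_majority_learner_anticorrelates(self):
        # Classic LOOCV artifact: holding out a positive tilts the training
        # balance negative, so a class-prior score anti-correlates with the
        # held-out label and the pooled AUC collapses to 0.
        d = _dataset(n_pos=5, n_neg=5, seed=4)
        rep = loocv(d, MajorityLearner(), seed=0)
        assert rep.auc == 0.0

    def test_report_json_round_trip(self):
        d = _dataset(seed=5)
        rep = cross_validate(d, _ThresholdLearner(), k=3, seed=5)
        import json

        obj = json.loads(rep.to_json())
        assert obj["comparison"] == d.name
        assert 0 <= obj["auc"] <= 1


class TestFriedman:
    def test_hand_example_perfect_ordering(self):
        # 3 algorithms, 4 comparisons, identical ordering everywhere:
        # mean ranks (1, 2, 3) -> chi2_F = 12*4/(3*4) * (14 - 12) = 8
        table = pd.DataFrame(
            {f"c{j}": [0.9, 0.8, 0.7] for j in range(4)},
            index=["best", "mid", "worst"],
        )
        res = friedman_compare(table)
        assert res.statistic == pytest.approx(8.0)
        assert res.mean_ranks["best"] == pytest.approx(1.0)
        assert res.mean_ranks["worst"] == pytest.approx(3.0)
        assert res.significant(0.05)

    def test_dunn_table_structure(self):
        table = pd.DataFrame(
            {"c1": [0.9, 0.5, 0.1], "c2": [0.8, 0.6, 0.2], "c3": [0.7, 0.4, 0.3]},
            index=["a", "b", "c"],
        )
        res = friedman_compare(table)
        assert len(res.dunn) == 3  # all pairs
        assert (res.dunn["pvalue_adjusted"] >= res.dunn["pvalue"] - 1e-12).all()
        assert (res.dunn["pvalue_adjusted"] <= 1.0).all()

    def test_ties_use_average_ranks(self):
        table = pd.DataFrame(
            {"c1": [0.5, 0.5], "c2": [0.5, 0.5]}, index=["a", "b"]
        )
        res = friedman_compare(table)
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_needs_two_by_two(self):
        with pytest.raises(ValueError):
            friedman_compare(pd.DataFrame({"c1": [0.1, 0.2]}))


def test_reports_to_table_columns():
    d = _dataset(seed=6)
    reps = [cross_validate(d, _ThresholdLearner(), k=2, seed=s) for s in (0, 1)]
    reps[0].method, reps[1].method = "m1", "m2"
    table = reports_to_table(reps)
    assert set(table.columns) >= {"method", "comparison", "acc", "f1", "auc"}
    assert len(table) == 2
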