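"""Classifier bench: splitting, training, confusion metrics, ROC, selection."""

import math
import warnings

import numpy as np
import pytest

from premirscan.classify import (ALGORITHMS, ConfusionCounts, MetricsReport,
                                 evaluate, metrics_from_counts, roc_curve,
                                 select_best, split_dataset, train_classifier)
from premirscan.kmers import FeatureMatrix, enumerate_kmers


def _matrix(X, labels, k=1):
    X = np.asarray(X, dtype=float)
    return FeatureMatrix(X=X, labels=np.asarray(labels),
                         ids=[f"s{i}" for i in range(len(labels))],
                         feature_names=enumerate_kmers(k)[: X.shape[1]])


def _separable(n_per_class=10, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal([0.9, 0.1], 0.02, size=(n_per_class, 2))
    b = rng.normal([0.1, 0.9], 0.02, size=(n_per_class, 2))
    return _matrix(np.vstack([a, b]), [1] * n_per_class + [0] * n_per_class)


class TestSplit:
    def test_stratified_70_30(self):
        train, test = split_dataset(_separable(10), 0.7, seed=0)
        assert (train.labels == 1).sum() == 7 and (train.labels == 0).sum() == 7
        assert (test.labels == 1).sum() == 3 and (test.labels == 0).sum() == 3

    def test_partition_law_and_determinism(self):
        fm = _separable(50)
        t1, e1 = split_dataset(fm, 0.7, seed=3)
        t2, e2 = split_dataset(fm, 0.7, seed=3)
        assert t1.ids == t2.ids and e1.ids == e2.ids
        assert set(t1.ids) | set(e1.ids) == set(fm.ids)
        assert not set(t1.ids) & set(e1.ids)

    def test_tiny_class_rejected(self):
        fm = _matrix([[0.1, 0.9], [0.9, 0.1], [0.5, 0.5]], [1, 0, 0])
        with pytest.raises(ValueError):
            split_dataset(fm, 0.7, seed=0)


class TestTrain:
    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_separable_data_learned(self, algorithm):
        fm = _separable(20)
        model = train_classifier(fm, algorithm, seed=0)
        report = evaluate(model, fm)
        assert report.accuracy == 1.0

    def test_knn_one_neighbor_memorizes(self):
        fm = _separable(10)
        model = train_classifier(fm, "KNN", hyperparams={"n_neighbors": 1}, seed=0)
        pred = model.predict_proba_positive(fm.X) >= 0.5
        assert np.array_equal(pred.astype(int), fm.labels)

    def test_single_class_rejected(self):
        fm = _matrix([[0.1, 0.9], [0.2, 0.8]], [1, 1])
        with pytest.raises(ValueError):
            train_classifier(fm, "SVM")

    def test_deterministic_given_seed(self):
        fm = _separable(30, seed=5)
        p1 = train_classifier(fm, "SVM", seed=2).predict_proba_positive(fm.X)
        p2 = train_classifier(fm, "SVM", seed=2).predict_proba_positive(fm.X)
        assert np.array_equal(p1, p2)


class TestMetrics:
    @pytest.mark.parametrize("counts,expected", [
        ((10, 0, 10, 0), (1.0, 1.0, 1.0, 1.0)),
        ((5, 5, 5, 5), (0.5, 0.5, 0.5, 0.5)),
        ((3, 1, 4, 2), (0.75, 0.7, 0.6, 2 * (0.75 * 0.6) / (0.75 + 0.6))),
    ])
    def test_hand_computed_confusions(self, counts, expected):
        r = metrics_from_counts(ConfusionCounts(*counts))
        assert (r.precision, r.accuracy, r.recall, r.f_measure) == \
            pytest.approx(expected)

    def test_zero_denominators_are_nan_with_warning(self):
        with pytest.warns(UserWarning, match="precision undefined"):
            r = metrics_from_counts(ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
        assert math.isnan(r.precision) and math.isnan(r.f_measure)
        assert r.accuracy == 0.5

    def test_row_order_invariance(self):
        fm = _separable(20, seed=7)
        model = train_classifier(fm, "RF", seed=0)
        perm = np.random.default_rng(0).permutation(len(fm))
        r1, r2 = evaluate(model, fm), evaluate(model, fm.subset(perm))
        assert r1.confusion == r2.confusion


class _StubModel:
    """Fixed per-row probabilities, for ROC geometry checks."""

    def __init__(self, proba):
        self.proba = np.asarray(proba, dtype=float)
        self.algorithm = "stub"

    def predict_proba_positive(self, X):
        return self.proba[: len(X)]


class TestRoc:
    def test_perfect_and_anti_and_random(self):
        fm = _matrix(np.zeros((6, 2)), [1, 1, 1, 0, 0, 0])
        assert roc_curve(_StubModel(fm.labels.astype(float)), fm).auc == 1.0
        assert roc_curve(_StubModel(1.0 - fm.labels), fm).auc == 0.0
        assert roc_curve(_StubModel(np.full(6, 0.4)), fm).auc == 0.5

    def test_one_class_rejected(self):
        fm = _matrix(np.zeros((3, 2)), [1, 1, 1])
        with pytest.raises(ValueError):
            roc_curve(_StubModel([0.1, 0.2, 0.3]), fm)

    def test_curve_monotone_between_corners(self):
        fm = _matrix(np.zeros((8, 2)), [1, 0, 1, 0, 1, 1, 0, 0])
        rc = roc_curve(_StubModel([0.9, 0.8, 0.7, 0.2, 0.6, 0.4, 0.3, 0.1]), fm)
        assert np.all(np.diff(rc.fpr) >= 0) and np.all(np.diff(rc.tpr) >= 0)
        assert (rc.fpr[0], rc.tpr[0]) == (0.0, 0.0)
        assert (rc.fpr[-1], rc.tpr[-1]) == (1.0, 1.0)


def _report(alg, f, acc):
    return MetricsReport(algorithm=alg, confusion=ConfusionCounts(1, 1, 1, 1),
                         precision=0.5, accuracy=acc, recall=0.5, f_measure=f)


class TestSelectBest:
    def test_highest_f_wins(self):
        assert select_best([_report("RF", 0.9, 0.9), _report("KNN", 0.8, 0.95)]) == "RF"

    def test_accuracy_breaks_f_ties(self):
        assert select_best([_report("RF", 0.9, 0.90), _report("KNN", 0.9, 0.95)]) == "KNN"

    def test_fixed_order_breaks_remaining_ties(self):
        reports = [_report(a, 0.9, 0.9) for a in ("NB", "KNN", "SVM", "RF")]
        assert select_best(reports) == "SVM"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best([])
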