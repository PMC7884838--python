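"""Classifier bench for pre-miRNA vs. coding discrimination.

Five algorithms are trained on k-mer frequency matrices and compared with the
standard confusion-matrix metrics:

    precision = TP / (TP + FP)
    accuracy  = (TP + TN) / (TP + TN + FN + FP)
    recall    = TP / (TP + FN)
    F-measure = 2 * precision * recall / (precision + recall)

Zero-denominator cases are reported as NaN with a warning — an undefined
precision is not a precision of zero. The best model is selected by F-measure,
ties broken by accuracy, then by a fixed algorithm order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .kmers import FeatureMatrix

#: fixed algorithm order, also the final tie-break in model selection
ALGORITHMS: tuple[str, ...] = ("SVM", "RF", "XGBoost", "KNN", "NB")


def split_dataset(
    matrix: FeatureMatrix, train_fraction: float = 0.7, seed: int = 0
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Stratified train/test partition (70/30 by default), deterministic in seed."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    classes, counts = np.unique(matrix.labels, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 rows in each of two classes to stratify")
    idx = np.arange(len(matrix))
    train_idx, test_idx = train_test_split(
        idx, train_size=train_fraction, stratify=matrix.labels, random_state=seed
    )
    return matrix.subset(np.sort(train_idx)), matrix.subset(np.sort(test_idx))


def make_estimator(algorithm: str, seed: int = 0, hyperparams: dict | None = None):
    """Library-default estimator for one of the five benched algorithms."""
    hp = dict(hyperparams or {})
    if algorithm == "SVM":
        return SVC(kernel="rbf", probability=True, random_state=seed, **hp)
    if algorithm == "RF":
        return RandomForestClassifier(random_state=seed, **hp)
    if algorithm == "NB":
        return GaussianNB(**hp)
    if algorithm == "XGBoost":
        return XGBClassifier(random_state=seed, eval_metric="logloss", **hp)
    if algorithm == "KNN":
        return KNeighborsClassifier(**hp)
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")


@dataclass
class TrainedModel:
    """A fitted classifier plus the metadata needed to reuse it downstream."""

    algorithm: str
    estimator: object
    feature_names: list[str]
    seed: int
    hyperparams: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.feature_names[0])

    def predict_proba_positive(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"model expects {len(self.feature_names)} features, got {X.shape[1]}"
            )
        proba = self.estimator.predict_proba(X)
        pos_col = list(self.estimator.classes_).index(1)
        return proba[:, pos_col]


def train_classifier(
    train: FeatureMatrix, algorithm: str,
    hyperparams: dict | None = None, seed: int = 0,
) -> TrainedModel:
    if len(np.unique(train.labels)) < 2:
        raise ValueError("training data must contain both classes")
    est = make_estimator(algorithm, seed=seed, hyperparams=hyperparams)
    est.fit(train.X, train.labels)
    return TrainedModel(
        algorithm=algorithm, estimator=est, feature_names=list(train.feature_names),
        seed=seed, hyperparams=dict(hyperparams or {}),
    )


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    algorithm: str
    confusion: ConfusionCounts
    precision: float
    accuracy: float
    recall: float
    f_measure: float


def metrics_from_counts(counts: ConfusionCounts, algorithm: str = "") -> MetricsReport:
    """Confusion counts -> precision/accuracy/recall/F, NaN where undefined."""

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reported as NaN")
            return math.nan
        return num / den

    precision = ratio(counts.tp, counts.tp + counts.fp, "precision")
    recall = ratio(counts.tp, counts.tp + counts.fn, "recall")
    accuracy = ratio(counts.tp + counts.tn, counts.total, "accuracy")
    if math.isnan(precision) or math.isnan(recall):
        f = math.nan
        warnings.warn("F-measure undefined; reported as NaN")
    elif precision + recall == 0:
        f = math.nan
        warnings.warn("F-measure undefined (precision + recall = 0); reported as NaN")
    else:
        f = 2 * precision * recall / (precision + recall)
    return MetricsReport(algorithm=algorithm, confusion=counts, precision=precision,
                         accuracy=accuracy, recall=recall, f_measure=f)


def evaluate(model: TrainedModel, test: FeatureMatrix, threshold: float = 0.5) -> MetricsReport:
    """Confusion counts at the probability threshold (default 0.5) and the metrics."""
    if len(test) == 0:
        raise ValueError("test set is empty")
    proba = model.predict_proba_positive(test.X)
    pred = (proba >= threshold).astype(int)
    y = test.labels
    counts = ConfusionCounts(
        tp=int(np.sum((pred == 1) & (y == 1))),
        fp=int(np.sum((pred == 1) & (y == 0))),
        tn=int(np.sum((pred == 0) & (y == 0))),
        fn=int(np.sum((pred == 0) & (y == 1))),
    )
    return metrics_from_counts(counts, algorithm=model.algorithm)


@dataclass(frozen=True)
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_curve(model: TrainedModel, test: FeatureMatrix) -> RocCurve:
    """ROC over all distinct predicted probabilities; AUC by the trapezoidal rule."""
    if len(np.unique(test.labels)) < 2:
        raise ValueError("ROC requires both classes in the test set")
    proba = model.predict_proba_positive(test.X)
    fpr, tpr, thr = _sk_roc_curve(test.labels, proba, drop_intermediate=False)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(_auc(fpr, tpr)))


def select_best(reports: Sequence[MetricsReport]) -> str:
    """Best algorithm by F-measure, then accuracy, then fixed algorithm order."""
    if not reports:
        raise ValueError("no reports to select from")

    def order_rank(r: MetricsReport) -> int:
        return ALGORITHMS.index(r.algorithm) if r.algorithm in ALGORITHMS else len(ALGORITHMS)

    def key(item):
        i, r = item
        f = -math.inf if math.isnan(r.f_measure) else r.f_measure
        a = -math.inf if math.isnan(r.accuracy) else r.accuracy
        return (-f, -a, order_rank(r), i)

    return min(enumerate(reports), key=key)[1].algorithm


def bench(
    matrix: FeatureMatrix, seed: int = 0, train_fraction: float = 0.7,
    algorithms: Sequence[str] = ALGORITHMS,
) -> tuple[list[MetricsReport], dict[str, TrainedModel], dict[str, RocCurve]]:
    """Train and evaluate every algorithm on one stratified split."""
    train, test = split_dataset(matrix, train_fraction=train_fraction, seed=seed)
    reports, models, rocs = [], {}, {}
    for alg in algorithms:
        model = train_classifier(train, alg, seed=seed)
        models[alg] = model
        reports.append(evaluate(model, test))
        rocs[alg] = roc_curve(model, test)
    return reports, models, rocs


def reports_to_tsv(reports: Sequence[MetricsReport], path) -> None:
    with open(path, "w") as fh:
        fh.write("algorithm\ttp\tfp\ttn\tfn\tprecision\taccuracy\trecall\tf_measure\n")
        for r in reports:
            c = r.confusion
            fh.write(
                f"{r.algorithm}\t{c.tp}\t{c.fp}\t{c.tn}\t{c.fn}\t"
                f"{r.precision:.6f}\t{r.accuracy:.6f}\t{r.recall:.6f}\t{r.f_measure:.6f}\n"
            )
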