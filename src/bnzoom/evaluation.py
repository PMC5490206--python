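"""Confusion-matrix metrics and the BN-vs-logistic model comparison."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .cohort import CohortTable
from .estimators import BNTreatmentClassifier, LogisticTreatmentBaseline
from .network import BayesianNetwork
from .schema import BCSR


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int
    positive_label: str

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class PerformanceMetrics:
    """Accuracy, sensitivity (TPR), specificity (TNR).

    A metric whose denominator is zero is NaN and its name is recorded in
    ``undefined`` rather than silently reported as 0.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    undefined: frozenset[str] = field(default_factory=frozenset)

    def to_json(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "undefined": sorted(self.undefined),
        }


def confusion(
    pred: Sequence[str], truth: Sequence[str], positive: str = BCSR
) -> ConfusionMatrix:
    if len(pred) != len(truth):
        raise ValueError("pred and truth must have equal length")
    tp = fp = tn = fn = 0
    for p, t in zip(pred, truth):
        if t == positive:
            tp += p == positive
            fn += p != positive
        else:
            tn += p != positive
            fp += p == positive
    return ConfusionMatrix(tp, fp, tn, fn, positive)


def metrics(cm: ConfusionMatrix) -> PerformanceMetrics:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    undefined = set()
    accuracy = (cm.tp + cm.tn) / cm.total
    if cm.tp + cm.fn > 0:
        sensitivity = cm.tp / (cm.tp + cm.fn)
    else:
        sensitivity = math.nan
        undefined.add("sensitivity")
    if cm.tn + cm.fp > 0:
        specificity = cm.tn / (cm.tn + cm.fp)
    else:
        specificity = math.nan
        undefined.add("specificity")
    return PerformanceMetrics(accuracy, sensitivity, specificity, frozenset(undefined))


def _split_xy(table: CohortTable) -> tuple[pd.DataFrame, pd.Series]:
    t_name = table.schema.treatment.name
    X = table.records.drop(columns=[t_name])
    y = table.records[t_name]
    return X, y


def fit_logistic_baseline(
    train: CohortTable,
    reference_levels: dict | None = None,
    exclude: tuple = (),
) -> LogisticTreatmentBaseline:
    """Fit the indicator-coded logistic baseline on a cohort's train split."""
    X, y = _split_xy(train)
    model = LogisticTreatmentBaseline(
        reference_levels=reference_levels, exclude=exclude
    )
    return model.fit(X, y)


def _bn_predictions(bn, test: CohortTable, exclude: tuple):
    if isinstance(bn, BayesianNetwork):
        clf = BNTreatmentClassifier(
            structure="fixed", dag=bn.dag, schema=bn.schema, exclude=exclude
        )
        clf.schema_ = bn.schema
        clf.network_ = bn
        clf.dag_ = bn.dag
        clf.classes_ = pd.Index(sorted(bn.schema.treatment.categories)).to_numpy()
    else:
        clf = bn
    X, _ = _split_xy(test)
    return clf.predict(X)


def compare_models(
    bn,
    lr: LogisticTreatmentBaseline,
    test: CohortTable,
    positive: str = BCSR,
    exclude: tuple = (),
) -> dict:
    """Predict every test record with both models; paired metric triples.

    ``bn`` may be a fitted :class:`BayesianNetwork` or a fitted
    :class:`BNTreatmentClassifier`.
    """
    X, y = _split_xy(test)
    truth = list(y)
    bn_pred = list(_bn_predictions(bn, test, exclude))
    lr_pred = list(lr.predict(X))
    bn_cm = confusion(bn_pred, truth, positive)
    lr_cm = confusion(lr_pred, truth, positive)
    return {
        "bn": {"confusion": bn_cm, "metrics": metrics(bn_cm)},
        "lr": {"confusion": lr_cm, "metrics": metrics(lr_cm)},
    }
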