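"""Benchmark metrics: confusion matrices, ACC, MCC, ROC/AUC, prioritization
enrichment and dataset-overlap analysis.

Conventions: a sequence is predicted soluble when its score is >= the
threshold; MCC returns 0 when any confusion-matrix marginal is zero (the
formula's denominator vanishes); prioritization keeps the top ``ceil(f*n)``
scores and compares observed true positives with the analytic random-
selection baseline ``f*n*prevalence``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .seqio import SOLUBLE, ProteinRecord


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp


def confusion_at_threshold(
    scores: Sequence[float], labels: Sequence[int], t: float
) -> ConfusionMatrix:
    """Confusion matrix with predicted-soluble = score >= t."""
    if len(scores) != len(labels):
        raise ValueError("scores and labels differ in length")
    tp = tn = fp = fn = 0
    for s, y in zip(scores, labels):
        pred = s >= t
        if pred and y:
            tp += 1
        elif pred and not y:
            fp += 1
        elif not pred and y:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp, tn, fp, fn)


def accuracy(cm: ConfusionMatrix) -> float:
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    return (cm.tp + cm.tn) / cm.n


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient; 0 when any marginal is zero."""
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    denom = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    if denom == 0:
        return 0.0
    return (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(denom)


def roc_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[list[tuple[float, float]], float]:
    """ROC points (fpr, tpr) from (0,0) to (1,1) and the trapezoidal AUC.

    The trapezoidal AUC over the full ROC equals the tie-corrected
    Mann-Whitney statistic divided by n_pos * n_neg.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes")
    fpr, tpr, _ = _roc_curve(labels, np.asarray(scores, dtype=float))
    points = list(zip(fpr.tolist(), tpr.tolist()))
    if points[0] != (0.0, 0.0):
        points.insert(0, (0.0, 0.0))
    return points, float(_trapezoid_auc(fpr, tpr))


@dataclass(frozen=True)
class EvalReport:
    confusion: ConfusionMatrix
    acc: float
    mcc: float
    auc: float
    roc: tuple
    threshold: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "AUC": round(self.auc, 4),
                "T": self.threshold,
                "ACC": round(self.acc, 4),
                "MCC": round(self.mcc, 4),
                "TP": self.confusion.tp,
                "TN": self.confusion.tn,
                "FP": self.confusion.fp,
                "FN": self.confusion.fn,
            },
            indent=2,
        )


def evaluate(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> EvalReport:
    """Full benchmark report at a score threshold."""
    cm = confusion_at_threshold(scores, labels, threshold)
    roc, auc_val = roc_auc(scores, labels)
    return EvalReport(
        confusion=cm,
        acc=accuracy(cm),
        mcc=mcc(cm),
        auc=auc_val,
        roc=tuple(roc),
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# prioritization enrichment

@dataclass(frozen=True)
class PrioritizationCurve:
    """True-positive enrichment of score-ranked selection over random picks."""

    fractions: tuple[float, ...]
    tp_observed: tuple[int, ...]
    tp_baseline: tuple[float, ...]
    enrichment: tuple[float, ...]


def prioritization(
    scores: Sequence[float],
    labels: Sequence[int],
    fractions: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
) -> PrioritizationCurve:
    """Enrichment of true positives among the top-scoring fraction.

    At each fraction f the top ceil(f*n) scores are kept (descending stable
    sort, so ties preserve input order); observed positives among the kept
    are compared with the exact random-selection expectation f*n*prevalence.
    Enrichment = observed/baseline - 1.
    """
    n = len(scores)
    if n == 0:
        raise ValueError("empty input")
    if any(not 0.0 < f <= 1.0 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    labels_arr = np.asarray(labels)
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    prevalence = labels_arr.sum() / n
    observed: list[int] = []
    baseline: list[float] = []
    enrich: list[float] = []
    for f in fractions:
        k = math.ceil(f * n)
        tp_obs = int(labels_arr[order[:k]].sum())
        tp_base = f * n * prevalence
        observed.append(tp_obs)
        baseline.append(tp_base)
        enrich.append(tp_obs / tp_base - 1.0 if tp_base > 0 else float("nan"))
    return PrioritizationCurve(
        tuple(fractions), tuple(observed), tuple(baseline), tuple(enrich)
    )


# ---------------------------------------------------------------------------
# dataset overlap / annotation disagreement

@dataclass(frozen=True)
class OverlapReport:
    """Exact-sequence overlap of set B with reference set A.

    For shared sequences, B's labels are scored against A's (A taken as the
    truth), as a confusion matrix: e.g. fn counts sequences soluble in A but
    insoluble in B.
    """

    n_a: int
    n_b: int
    n_overlap: int
    overlap_fraction: float
    confusion: ConfusionMatrix


def dataset_overlap(
    set_a: Sequence[ProteinRecord], set_b: Sequence[ProteinRecord]
) -> OverlapReport:
    a_by_seq: dict[str, str] = {}
    for rec in set_a:
        if rec.label is None:
            raise ValueError(f"unlabeled record {rec.id!r} in set A")
        a_by_seq[rec.sequence] = rec.label
    tp = tn = fp = fn = 0
    matched: set[str] = set()
    for rec in set_b:
        if rec.label is None:
            raise ValueError(f"unlabeled record {rec.id!r} in set B")
        truth = a_by_seq.get(rec.sequence)
        if truth is None or rec.sequence in matched:
            continue
        matched.add(rec.sequence)
        if truth == SOLUBLE:
            if rec.label == SOLUBLE:
                tp += 1
            else:
                fn += 1
        else:
            if rec.label == SOLUBLE:
                fp += 1
            else:
                tn += 1
    n_overlap = len(matched)
    return OverlapReport(
        n_a=len(set_a),
        n_b=len(set_b),
        n_overlap=n_overlap,
        overlap_fraction=n_overlap / len(set_a) if set_a else 0.0,
        confusion=ConfusionMatrix(tp, tn, fp, fn),
    )
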