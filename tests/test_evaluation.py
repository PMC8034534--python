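"""Benchmark metrics: confusion/ACC/MCC against the published benchmark
table, ROC-AUC against a Mann-Whitney oracle, prioritization enrichment."""

import numpy as np
import pytest

from oracles import mann_whitney_auc
from soluprot.evaluation import (
    ConfusionMatrix,
    accuracy,
    confusion_at_threshold,
    dataset_overlap,
    evaluate,
    mcc,
    prioritization,
    roc_auc,
)
from soluprot.seqio import INSOLUBLE, SOLUBLE, ProteinRecord

from tests_table import BENCHMARK_TABLE  # printed 12-row benchmark fixture


def test_confusion_hand_example():
    cm = confusion_at_threshold([0.9, 0.6, 0.4, 0.1], [1, 0, 1, 0], 0.5)
    assert (cm.tp, cm.fp, cm.fn, cm.tn) == (1, 1, 1, 1)


def test_confusion_all_positive():
    cm = confusion_at_threshold([1.0] * 5, [1] * 5, 0.5)
    assert cm.tp == 5 and cm.n == 5


def test_confusion_length_mismatch():
    with pytest.raises(ValueError):
        confusion_at_threshold([0.5], [1, 0], 0.5)


def test_threshold_boundary_is_inclusive():
    cm = confusion_at_threshold([0.5], [1], 0.5)
    assert cm.tp == 1  # score == threshold predicts soluble


@pytest.mark.parametrize(
    "method,auc,t,acc_pct,mcc_val,tp,tn,fp,fn", BENCHMARK_TABLE
)
def test_benchmark_table_regression(method, auc, t, acc_pct, mcc_val, tp, tn, fp, fn):
    """Printed ACC and MCC are recomputable from the printed confusion counts,
    and the balanced test set gives marginals tp+fn = tn+fp = 1550."""
    cm = ConfusionMatrix(tp, tn, fp, fn)
    assert cm.n == 3100
    assert cm.positives == 1550 and cm.negatives == 1550
    assert 100 * accuracy(cm) == pytest.approx(acc_pct, abs=0.05 + 1e-9)
    assert mcc(cm) == pytest.approx(mcc_val, abs=0.005 + 1e-9)


def test_mcc_symmetric_and_degenerate():
    assert mcc(ConfusionMatrix(5, 5, 5, 5)) == 0.0
    assert mcc(ConfusionMatrix(5, 0, 0, 5)) == 0.0  # zero marginal convention
    with pytest.raises(ValueError):
        accuracy(ConfusionMatrix(0, 0, 0, 0))


def test_roc_auc_reference_cases():
    _, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert auc == 1.0
    _, auc = roc_auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0])
    assert auc == 0.5  # all ties give chance level
    _, auc = roc_auc([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0])
    assert auc == pytest.approx(0.75)  # 3 of 4 pos/neg pairs ordered correctly


def test_roc_curve_endpoints_and_monotonicity():
    points, _ = roc_auc([0.9, 0.4, 0.6, 0.2, 0.5], [1, 0, 1, 0, 1])
    assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)
    fpr = [p[0] for p in points]
    tpr = [p[1] for p in points]
    assert fpr == sorted(fpr) and tpr == sorted(tpr)


def test_roc_single_class_rejected():
    with pytest.raises(ValueError):
        roc_auc([0.1, 0.2], [1, 1])


@pytest.mark.parametrize("seed", range(10))
def test_roc_auc_matches_mann_whitney_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 51))
    labels = rng.integers(0, 2, n)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    # quantized scores force ties to exercise the half-credit correction
    scores = np.round(rng.random(n), 1)
    _, auc = roc_auc(scores, labels)
    assert auc == pytest.approx(mann_whitney_auc(scores, labels))


def test_prioritization_analytic_baseline():
    # a balanced set of 3100: random top-10% selection expects 155 positives
    labels = [1] * 1550 + [0] * 1550
    scores = list(np.linspace(1, 0, 3100))
    curve = prioritization(scores, labels, fractions=(0.1,))
    assert curve.tp_baseline[0] == pytest.approx(155.0)
    # a perfect scorer keeps only positives: 310 kept, enrichment 1.0
    perfect = [float(y) for y in labels]
    curve = prioritization(perfect, labels, fractions=(0.1,))
    assert curve.tp_observed[0] == 310
    assert curve.enrichment[0] == pytest.approx(1.0)


def test_prioritization_random_scores_null():
    rng = np.random.default_rng(0)
    labels = [1] * 200 + [0] * 200
    enr = []
    for _ in range(10):
        scores = rng.random(400)
        enr.append(prioritization(scores, labels, fractions=(0.2,)).enrichment[0])
    assert abs(np.mean(enr)) < 0.1  # no enrichment in expectation


def test_prioritization_input_validation():
    with pytest.raises(ValueError):
        prioritization([], [])
    with pytest.raises(ValueError):
        prioritization([0.5], [1], fractions=(0.0,))


def test_evaluate_report_consistency():
    scores = [0.9, 0.6, 0.4, 0.1]
    labels = [1, 0, 1, 0]
    report = evaluate(scores, labels, threshold=0.5)
    assert report.acc == 0.5
    assert report.confusion.n == 4
    assert 0.0 <= report.auc <= 1.0


SEQ_A = "ACDEFGHIKLMNPQRSTVWYACDEF"
SEQ_B = "WYACDEFGHIKLMNPQRSTVWYACD"


def test_dataset_overlap_identical_and_disjoint():
    a = [ProteinRecord("a1", SEQ_A, SOLUBLE), ProteinRecord("a2", SEQ_B, INSOLUBLE)]
    rep = dataset_overlap(a, a)
    assert rep.overlap_fraction == 1.0
    assert rep.confusion.fn == rep.confusion.fp == 0
    b = [ProteinRecord("b1", SEQ_A[::-1], SOLUBLE)]
    assert dataset_overlap(a, b).n_overlap == 0


def test_dataset_overlap_disagreement_counts():
    a = [ProteinRecord("a1", SEQ_A, SOLUBLE)]
    b = [ProteinRecord("b1", SEQ_A, INSOLUBLE)]
    rep = dataset_overlap(a, b)
    assert rep.n_overlap == 1
    assert rep.confusion.fn == 1  # soluble in A, insoluble in B
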