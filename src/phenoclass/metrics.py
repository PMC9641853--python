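"""Classification metrics: confusion counts and the ten derived scores.

The report comprises accuracy, precision, recall, F1, the Matthews
correlation coefficient, ROC AUC, and the four rate quantities
TNR/FPR/FNR/TPR, each applied literally to the confusion counts:

    accuracy  = (TP+TN) / (TP+TN+FP+FN)
    precision = TP / (TP+FP)
    recall    = TP / (TP+FN)
    F1        = 2·precision·recall / (precision+recall)
    MCC       = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    TNR = TN/(TN+FP)   FPR = FP/(TN+FP)
    FNR = FN/(TP+FN)   TPR = TP/(TP+FN)

A zero denominator yields ``None`` ("undefined"), never a silent 0 —
report tables print such cells as "–".  ROC AUC is the rank-based
Mann–Whitney statistic (probability that a random positive outscores a
random negative, ties counted ½).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

POSITIVE = "active"


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricReport:
    """Scores derived from one confusion matrix; ``None`` = undefined."""

    accuracy: float | None
    precision: float | None
    recall: float | None
    f1: float | None
    mcc: float | None
    tnr: float | None
    fpr: float | None
    fnr: float | None
    tpr: float | None
    roc_auc: float | None = None

    def rounded(self, ndigits: int = 2) -> dict[str, float | None]:
        """Report-file view: values rounded (half away from zero, the
        convention of printed report tables), undefined kept as ``None``."""
        def _r(v):
            if v is None:
                return None
            scale = 10 ** ndigits
            return float(np.copysign(np.floor(abs(v) * scale + 0.5), v)) / scale
        return {k: _r(v) for k, v in self.__dict__.items()}


def confusion(true_labels, predicted_labels, positive: str = POSITIVE) -> ConfusionMatrix:
    """Tally confusion counts with ``positive`` as the positive class."""
    t = list(true_labels)
    p = list(predicted_labels)
    if len(t) != len(p):
        raise ValueError(f"label vectors differ in length: {len(t)} vs {len(p)}")
    tp = sum(1 for a, b in zip(t, p) if a == positive and b == positive)
    tn = sum(1 for a, b in zip(t, p) if a != positive and b != positive)
    fp = sum(1 for a, b in zip(t, p) if a != positive and b == positive)
    fn = sum(1 for a, b in zip(t, p) if a == positive and b != positive)
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def score(cm: ConfusionMatrix) -> MetricReport:
    """Apply the metric formulas to one confusion matrix.

    Any quantity whose denominator is zero (e.g. TNR when the dataset has
    no true inactives) is ``None``.
    """
    if cm.total < 1:
        raise ValueError("empty confusion matrix")
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    mcc_den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = None if mcc_den == 0 else (tp * tn - fp * fn) / np.sqrt(mcc_den)
    return MetricReport(
        accuracy=_ratio(tp + tn, cm.total),
        precision=precision,
        recall=recall,
        f1=f1,
        mcc=mcc,
        tnr=_ratio(tn, tn + fp),
        fpr=_ratio(fp, tn + fp),
        fnr=_ratio(fn, tp + fn),
        tpr=_ratio(tp, tp + fn),
    )


def roc_auc(scores, true_labels, positive: str = POSITIVE) -> float | None:
    """Rank-based ROC AUC of continuous scores against binary truth.

    Equals the probability that a uniformly chosen positive receives a
    higher score than a uniformly chosen negative, counting ties as ½;
    undefined (``None``) when the truth contains a single class.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray([1 if l == positive else 0 for l in true_labels])
    if len(s) != len(y):
        raise ValueError("scores and labels differ in length")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(s)                       # midranks handle ties as ½
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def score_predictions(true_labels, predicted_labels, scores=None,
                      positive: str = POSITIVE) -> MetricReport:
    """Confusion-based report, with ROC AUC attached when scores are given."""
    report = score(confusion(true_labels, predicted_labels, positive))
    if scores is not None:
        report = MetricReport(**{**report.__dict__,
                                 "roc_auc": roc_auc(scores, true_labels, positive)})
    return report
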