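"""Class-weighted binary cross-entropy and the imbalance-aware metric suite.

The loss for N proteins with labels ``y_i`` and predicted probabilities
``p_i`` is

    J = -(1/N) * sum_i [ w * y_i * log(p_i) + (1 - y_i) * log(1 - p_i) ]

with the positive-class weight ``w = (1 - pos_ratio) / pos_ratio`` derived
from the positive fraction of the training set, so each class contributes
equally to the expected gradient under the dataset's imbalance.  A variant
that multiplies *both* terms by ``w`` (which merely rescales the loss and
cannot rebalance anything) is available behind ``weight_both_terms`` for
comparison experiments.

Metrics: balanced accuracy (BACC), Matthews correlation coefficient (MCC),
area under the ROC curve (AUC) and area under the precision-recall curve
(AUPRC, computed as step-wise average precision).  AUPRC is the primary
model-selection metric throughout the package because the RBP datasets are
roughly 1:10 positive:negative.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

PROB_EPS = 1e-7


@dataclass
class LabeledScores:
    """Binary labels paired with predicted probabilities in (0, 1)."""

    y: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int).ravel()
        self.p = np.asarray(self.p, dtype=float).ravel()
        if self.y.shape != self.p.shape:
            raise ValueError("labels and probabilities must have equal length")
        if self.y.size == 0:
            raise ValueError("empty score set")
        if not np.all((self.y == 0) | (self.y == 1)):
            raise ValueError("labels must be binary")
        self.p = np.clip(self.p, PROB_EPS, 1.0 - PROB_EPS)

    @property
    def N(self) -> int:
        return self.y.size


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def N(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsReport:
    bacc: float
    mcc: float
    auc: float
    auprc: float
    counts: ConfusionCounts
    threshold: float = 0.5

    def to_json(self) -> str:
        d = {
            "bacc": self.bacc, "mcc": self.mcc, "auc": self.auc,
            "auprc": self.auprc, "threshold": self.threshold,
            "TP": self.counts.TP, "TN": self.counts.TN,
            "FP": self.counts.FP, "FN": self.counts.FN,
        }
        return json.dumps(d, indent=2)

    def to_tsv_line(self, label: str = "") -> str:
        head = f"{label}\t" if label else ""
        return (
            f"{head}{self.bacc:.6f}\t{self.mcc:.6f}\t{self.auc:.6f}\t"
            f"{self.auprc:.6f}\t{self.counts.TP}\t{self.counts.TN}\t"
            f"{self.counts.FP}\t{self.counts.FN}"
        )


def class_weight(pos_ratio: float) -> float:
    """Positive-class loss weight w = (1 - pos_ratio) / pos_ratio."""
    if not 0.0 < pos_ratio < 1.0:
        raise ValueError(f"pos_ratio must be in (0, 1), got {pos_ratio}")
    return (1.0 - pos_ratio) / pos_ratio


def weighted_bce(
    scores: LabeledScores, w: float = 1.0, weight_both_terms: bool = False
) -> float:
    """Weighted binary cross-entropy J (probabilities clamped at 1e-7)."""
    y, p = scores.y, scores.p
    neg_w = w if weight_both_terms else 1.0
    terms = w * y * np.log(p) + neg_w * (1 - y) * np.log(1 - p)
    return float(-terms.mean())


def bce_grad_wrt_logits(y: np.ndarray, p: np.ndarray, w: float) -> np.ndarray:
    """d(weighted BCE)/d(logit) for p = sigmoid(logit): positive items give
    w (p - 1) / N, negatives p / N."""
    N = y.size
    return np.where(y == 1, w * (p - 1.0), p) / N


def confusion(scores: LabeledScores, threshold: float = 0.5) -> ConfusionCounts:
    """Tally the confusion matrix; p >= threshold counts as positive."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    pred = scores.p >= threshold
    y = scores.y.astype(bool)
    return ConfusionCounts(
        TP=int(np.sum(pred & y)),
        TN=int(np.sum(~pred & ~y)),
        FP=int(np.sum(pred & ~y)),
        FN=int(np.sum(~pred & y)),
    )


def bacc(counts: ConfusionCounts) -> float:
    """Balanced accuracy: mean of sensitivity and specificity.  When a class
    is absent its term is taken as 0 and a warning is issued."""
    terms = []
    if counts.TP + counts.FN > 0:
        terms.append(counts.TP / (counts.TP + counts.FN))
    else:
        warnings.warn("BACC: no positive examples; sensitivity term set to 0")
        terms.append(0.0)
    if counts.TN + counts.FP > 0:
        terms.append(counts.TN / (counts.TN + counts.FP))
    else:
        warnings.warn("BACC: no negative examples; specificity term set to 0")
        terms.append(0.0)
    return 0.5 * (terms[0] + terms[1])


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    TP, TN, FP, FN = counts.TP, counts.TN, counts.FP, counts.FN
    denom2 = (TP + FP) * (TP + FN) * (TN + FP) * (TN + FN)
    if denom2 == 0:
        return 0.0
    return (TP * TN - FP * FN) / float(np.sqrt(denom2))


def roc_auc(scores: LabeledScores) -> float:
    """Area under the ROC curve (equals the Mann-Whitney probability that a
    random positive outscores a random negative, ties counting half)."""
    if scores.y.min() == scores.y.max():
        raise ValueError("ROC AUC needs both classes present")
    return float(roc_auc_score(scores.y, scores.p))


def auprc(scores: LabeledScores) -> float:
    """Area under the precision-recall curve as step-wise average precision
    (sum over descending-score prefixes of (R_k - R_{k-1}) * P_k), not the
    trapezoidal interpolation, which overestimates PR area."""
    if scores.y.sum() == 0:
        raise ValueError("AUPRC needs at least one positive")
    return float(average_precision_score(scores.y, scores.p))


def evaluate(scores: LabeledScores, threshold: float = 0.5) -> MetricsReport:
    """Full metric suite at one decision threshold."""
    counts = confusion(scores, threshold)
    return MetricsReport(
        bacc=bacc(counts),
        mcc=mcc(counts),
        auc=roc_auc(scores),
        auprc=auprc(scores),
        counts=counts,
        threshold=threshold,
    )
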