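"""ROC/AUC and threshold-based sensitivity/specificity.

The detection target throughout is **negative rechallenge**: scores are
posterior probabilities of negative rechallenge, sensitivity is the
proportion of true negative-rechallenge patients predicted negative, and
specificity the proportion of true positive-rechallenge patients predicted
positive.  This orientation follows the clinical reporting convention of
the underlying method and is deliberately not configurable — a silent axis
flip in this setting would invert a treatment recommendation.

AUC is the trapezoidal area under the ROC curve, which (with ties credited
0.5) equals the Mann-Whitney concordance probability: the chance that a
random negative-rechallenge patient outscores a random positive-rechallenge
patient.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import UndefinedMetricError
from .naive_bayes import NaiveBayesModel, posterior_negative
from .schema import LABELS, NEGATIVE, POSITIVE, Cohort


def _label_array(labels: Sequence[str]) -> np.ndarray:
    labels = np.asarray(labels, dtype=object)
    bad = [l for l in labels if l not in LABELS]
    if bad:
        raise UndefinedMetricError(f"labels must be negative/positive, got {bad[:3]}")
    return labels == NEGATIVE  # True = detection target


def roc_points(scores: Sequence[float], labels: Sequence[str]) -> list[tuple[float, float]]:
    """ROC curve of (false-positive-rate, true-positive-rate) points.

    Thresholds sweep the distinct score values from high to low; tied
    scores move along the curve together.  The curve starts at (0, 0) and
    ends at (1, 1).
    """
    target = _label_array(labels)
    scores = np.asarray(scores, dtype=float)
    if scores.shape != target.shape:
        raise ValueError("scores and labels differ in length")
    n_pos = int(target.sum())          # negative-rechallenge = detection target
    n_neg = int((~target).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC requires both outcome classes")
    order = np.argsort(-scores, kind="stable")
    scores, target = scores[order], target[order]
    # indices where the score changes: one ROC vertex per distinct score
    distinct = np.nonzero(np.diff(scores))[0]
    idx = np.r_[distinct, scores.size - 1]
    tp = np.cumsum(target)[idx]
    fp = np.cumsum(~target)[idx]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    return list(zip(fpr.tolist(), tpr.tolist()))


def auc(scores: Sequence[float], labels: Sequence[str]) -> float:
    """Area under the ROC curve by trapezoidal integration.

    Equal to the Mann-Whitney concordance over all (negative, positive)
    patient pairs with ties counted 0.5, and invariant under any strictly
    increasing transformation of the scores.
    """
    points = np.asarray(roc_points(scores, labels))
    return float(np.trapezoid(points[:, 1], points[:, 0]))


def confusion_counts(predictions: Sequence[str], labels: Sequence[str]) -> dict[str, int]:
    """Confusion counts with negative rechallenge as the detection target.

    TP = true negative-rechallenge predicted negative; FN missed negatives;
    TN = true positive-rechallenge predicted positive; FP = positives
    wrongly predicted negative.
    """
    truth = _label_array(labels)
    pred = _label_array(predictions)
    if truth.shape != pred.shape:
        raise ValueError("predictions and labels differ in length")
    return {
        "TP": int((truth & pred).sum()),
        "FN": int((truth & ~pred).sum()),
        "TN": int((~truth & ~pred).sum()),
        "FP": int((~truth & pred).sum()),
    }


def sensitivity_specificity(predictions: Sequence[str], labels: Sequence[str],
                            ) -> tuple[float, float]:
    """(sensitivity, specificity) as exact count ratios.

    Sensitivity: fraction of negative-rechallenge patients predicted
    negative.  Specificity: fraction of positive-rechallenge patients
    predicted positive.  Either rate is undefined (raises) when its class
    is absent.
    """
    c = confusion_counts(predictions, labels)
    if c["TP"] + c["FN"] == 0:
        raise UndefinedMetricError(
            "sensitivity undefined: no negative-rechallenge cases in the labels")
    if c["TN"] + c["FP"] == 0:
        raise UndefinedMetricError(
            "specificity undefined: no positive-rechallenge cases in the labels")
    return c["TP"] / (c["TP"] + c["FN"]), c["TN"] / (c["TN"] + c["FP"])


@dataclass
class ThresholdRow:
    """Operating point of the classifier at one score threshold."""

    threshold: float
    sensitivity: float
    specificity: float
    counts: dict[str, int]


@dataclass
class PerformanceReport:
    """AUC, the ROC curve and one confusion row per requested threshold."""

    auc: float
    roc: list[tuple[float, float]]
    per_threshold: list[ThresholdRow] = field(default_factory=list)
    n_scored: int = 0

    def to_json(self) -> dict:
        return {
            "detection_target": NEGATIVE + "_rechallenge",
            "threshold_rule": "predict negative iff score > threshold",
            "auc": self.auc,
            "n_scored": self.n_scored,
            "roc": [list(p) for p in self.roc],
            "per_threshold": [
                {"threshold": r.threshold, "sensitivity": r.sensitivity,
                 "specificity": r.specificity, "counts": r.counts}
                for r in self.per_threshold
            ],
        }

    def to_text(self) -> str:
        """Plain-text table with rates rendered as whole percentages
        (stored values keep full precision)."""
        lines = [
            "Score = posterior probability of NEGATIVE rechallenge "
            "(ADR does not recur); predict negative iff score > threshold.",
            f"n = {self.n_scored}    AUC = {self.auc:.3f}",
            f"{'threshold':>10} {'sens%':>6} {'spec%':>6} {'TP':>4} {'FN':>4} {'TN':>4} {'FP':>4}",
        ]
        for r in self.per_threshold:
            c = r.counts
            lines.append(
                f"{r.threshold:>10.3g} {round(100 * r.sensitivity):>6d} "
                f"{round(100 * r.specificity):>6d} "
                f"{c['TP']:>4d} {c['FN']:>4d} {c['TN']:>4d} {c['FP']:>4d}")
        return "\n".join(lines)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=2)
            fh.write("\n")

    def roc_tsv(self) -> str:
        lines = ["fpr\ttpr"] + [f"{f!r}\t{t!r}" for f, t in self.roc]
        return "\n".join(lines) + "\n"


def evaluate_scores(scores: Sequence[float], labels: Sequence[str],
                    thresholds: Sequence[float] = ()) -> PerformanceReport:
    """Build a :class:`PerformanceReport` from precomputed scores."""
    report = PerformanceReport(
        auc=auc(scores, labels),
        roc=roc_points(scores, labels),
        n_scored=len(list(scores)),
    )
    scores = np.asarray(scores, dtype=float)
    for t in thresholds:
        pred = [NEGATIVE if s > t else POSITIVE for s in scores]
        sens, spec = sensitivity_specificity(pred, labels)
        report.per_threshold.append(
            ThresholdRow(float(t), sens, spec, confusion_counts(pred, labels)))
    return report


def evaluate_at_thresholds(model: NaiveBayesModel, cohort: Cohort,
                           thresholds: Sequence[float] = (),
                           ) -> PerformanceReport:
    """Score every labelled record of ``cohort`` with the model's posterior
    of negative rechallenge and report AUC plus one operating point per
    threshold (tie at the threshold predicts positive)."""
    records = [r for r in cohort.records if r.label in LABELS]
    if not records:
        raise UndefinedMetricError("no labelled records to evaluate")
    scores = [posterior_negative(model, r) for r in records]
    labels = [r.label for r in records]
    return evaluate_scores(scores, labels, thresholds)
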