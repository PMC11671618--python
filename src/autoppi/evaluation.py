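"""Classifier evaluation: confusion matrices, ROC/AUC, PR, thresholds.

Conventions: a pair is predicted positive when its score is **greater
than or equal to** the threshold; the trapezoid AUC over the full
threshold sweep equals the Mann-Whitney concordance probability
``P(s_pos > s_neg) + 0.5 * P(s_pos = s_neg)``; the operating threshold
reported alongside F1 is the observed score maximizing F1 (lowest such
score on ties), with Youden's J available as an alternative rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import precision_recall_curve, roc_curve

THRESHOLD_RULES = ("f1", "youden")


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError(f"scores and labels must be aligned 1-d arrays "
                         f"(got {scores.shape} vs {labels.shape})")
    if scores.size == 0:
        raise ValueError("empty score vector")
    return scores, labels


def _require_both_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def confusion_at(scores, labels, threshold: float) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) with predicted positive <=> score >= threshold."""
    scores, labels = _validate(scores, labels)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    return tp, fp, tn, fn


def roc_auc(scores, labels) -> tuple[list[tuple[float, float]], float]:
    """ROC points (FPR, TPR) over all distinct thresholds and trapezoid AUC."""
    scores, labels = _validate(scores, labels)
    _require_both_classes(labels)
    fpr, tpr, _ = roc_curve(labels, scores)
    return list(zip(fpr.tolist(), tpr.tolist())), float(_trapezoid_auc(fpr, tpr))


def pr_curve(scores, labels) -> list[tuple[float, float]]:
    """(precision, recall) points swept over all distinct thresholds.

    At a fixed recall, lowering the threshold only adds false positives,
    so each achieved recall is reported with the best precision any
    threshold attains there (a perfect classifier thus shows precision 1
    at every achieved recall).  Recall decreases along the returned
    sweep; precision at recall -> 0 is 1 by convention.
    """
    scores, labels = _validate(scores, labels)
    _require_both_classes(labels)
    precision, recall, _ = precision_recall_curve(labels, scores)
    best: dict[float, float] = {}
    for p, r in zip(precision.tolist(), recall.tolist()):
        best[r] = max(best.get(r, 0.0), p)
    return [(best[r], r) for r in sorted(best, reverse=True)]


def _f1_accuracy(tp: int, fp: int, tn: int, fn: int) -> tuple[float, float]:
    denom = 2 * tp + fp + fn
    f1 = 2 * tp / denom if denom else 0.0
    return f1, (tp + tn) / (tp + fp + tn + fn)


def optimal_threshold(scores, labels, rule: str = "f1") -> tuple[float, float, float]:
    """Pick the operating threshold among observed scores.

    rule="f1": maximize F1; rule="youden": maximize TPR - FPR.  Ties go
    to the lowest threshold.  Returns (threshold, F1, accuracy) at the
    chosen point.
    """
    scores, labels = _validate(scores, labels)
    if rule not in THRESHOLD_RULES:
        raise ValueError(f"unknown rule {rule!r}; supported: {THRESHOLD_RULES}")
    best = None
    for t in np.unique(scores):
        tp, fp, tn, fn = confusion_at(scores, labels, t)
        f1, acc = _f1_accuracy(tp, fp, tn, fn)
        if rule == "f1":
            objective = f1
        else:
            tpr = tp / (tp + fn) if tp + fn else 0.0
            fpr = fp / (fp + tn) if fp + tn else 0.0
            objective = tpr - fpr
        if best is None or objective > best[0] + 1e-12:
            best = (objective, float(t), f1, acc)
    _, t, f1, acc = best
    return t, f1, acc


@dataclass
class EvaluationReport:
    """Everything a model-quality figure or summary table needs."""

    model_name: str
    n: int
    auc: float
    roc_points: list = field(repr=False, default_factory=list)
    pr_points: list = field(repr=False, default_factory=list)
    confusion_at_half: tuple[int, int, int, int] = (0, 0, 0, 0)
    optimal_threshold: float = 0.5
    f1_at_optimal: float = 0.0
    accuracy_at_optimal: float = 0.0

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate_scores(scores, labels, model_name: str = "model",
                    rule: str = "f1") -> EvaluationReport:
    scores, labels = _validate(scores, labels)
    _require_both_classes(labels)
    roc_points, auc_value = roc_auc(scores, labels)
    t, f1, acc = optimal_threshold(scores, labels, rule=rule)
    return EvaluationReport(
        model_name=model_name,
        n=int(scores.size),
        auc=auc_value,
        roc_points=roc_points,
        pr_points=pr_curve(scores, labels),
        confusion_at_half=confusion_at(scores, labels, 0.5),
        optimal_threshold=t,
        f1_at_optimal=f1,
        accuracy_at_optimal=acc,
    )


def plot_curves(report: EvaluationReport, roc_path, pr_path) -> None:
    """Write ROC and PR curve figures (PNG/PDF by extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    for p in (roc_path, pr_path):
        Path(p).parent.mkdir(parents=True, exist_ok=True)

    fpr, tpr = zip(*report.roc_points)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fpr, tpr, label=f"AUC = {report.auc:.3f}")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set(xlabel="False positive rate", ylabel="True positive rate",
           title=f"ROC — {report.model_name}")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(roc_path)
    plt.close(fig)

    precision, recall = zip(*report.pr_points)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(recall, precision)
    ax.set(xlabel="Recall", ylabel="Precision", ylim=(0, 1.05),
           title=f"PR — {report.model_name}")
    fig.tight_layout()
    fig.savefig(pr_path)
    plt.close(fig)
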