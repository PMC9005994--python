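"""Binary classification metrics, ROC/PRC curves and FPR-matched thresholds.

Scalar metrics follow the standard confusion-count definitions:

    Sen = TP/(TP+FN)            Spe = TN/(TN+FP)
    Pre = TP/(TP+FP)            Acc = (TP+TN)/total
    F1  = 2TP/(2TP+FP+FN)       FOR = FN/(FN+TN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Zero-denominator conventions (all documented, none raise): Pre = 0 when no
positive predictions, FOR = 0 when no negative predictions, MCC = 0 when any
denominator factor vanishes.

The decision rule is ``score >= threshold`` (a score exactly at the
threshold is called positive).  AUROC equals the Mann-Whitney pair
statistic; AUPRC uses step-wise summation (average precision), the standard
for precision-recall curves.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _validate(y_true, scores) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("y_true and scores must have equal length")
    if y.size == 0:
        raise ValueError("empty input")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be 0/1")
    return y, s


def confusion(y_true, scores, threshold: float = 0.5) -> ConfusionCounts:
    """Count the confusion table under the ``score >= threshold`` rule."""
    y, s = _validate(y_true, scores)
    pred = s >= threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & (y == 1))),
        fp=int(np.sum(pred & (y == 0))),
        tn=int(np.sum(~pred & (y == 0))),
        fn=int(np.sum(~pred & (y == 1))),
    )


def metrics(c: ConfusionCounts) -> dict[str, float]:
    """The seven scalar metrics from confusion counts."""
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    sen = tp / (tp + fn) if tp + fn else 0.0
    spe = tn / (tn + fp) if tn + fp else 0.0
    pre = tp / (tp + fp) if tp + fp else 0.0
    acc = (tp + tn) / c.total if c.total else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fn * fp) / math.sqrt(den) if den else 0.0
    for_ = fn / (fn + tn) if fn + tn else 0.0
    return {
        "Sen": sen,
        "Spe": spe,
        "Pre": pre,
        "Acc": acc,
        "F1": f1,
        "MCC": mcc,
        "FOR": for_,
    }


def roc(y_true, scores) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) and AUROC (= Mann-Whitney pair statistic)."""
    y, s = _validate(y_true, scores)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(y, s)
    return np.column_stack([fpr, tpr]), float(roc_auc_score(y, s))


def prc(y_true, scores) -> tuple[np.ndarray, float]:
    """Precision-recall points and step-wise AUPRC (average precision)."""
    y, s = _validate(y_true, scores)
    if not np.any(y == 1):
        raise ValueError("PRC needs at least one positive")
    precision, recall, _ = precision_recall_curve(y, s)
    return np.column_stack([recall, precision]), float(
        average_precision_score(y, s)
    )


def threshold_for_fpr(y_true, scores, target_fpr: float) -> float:
    """Smallest threshold whose empirical false-positive rate <= target.

    Under the ``score >= t`` rule FPR is non-increasing in t, so the result
    is the most permissive operating point still meeting the FPR budget.
    """
    y, s = _validate(y_true, scores)
    if not 0 < target_fpr <= 1:
        raise ValueError("target_fpr must be in (0, 1]")
    neg = s[y == 0]
    if neg.size == 0:
        raise ValueError("no negatives to estimate FPR from")
    candidates = np.unique(s)
    for t in candidates:  # ascending: first hit is the smallest threshold
        if np.mean(neg >= t) <= target_fpr:
            return float(t)
    return float(np.nextafter(neg.max(), np.inf))


@dataclasses.dataclass
class MetricsReport:
    """Confusion counts, scalar metrics, and both curves with their areas."""

    counts: ConfusionCounts
    scalars: dict[str, float]
    auroc: float
    auprc: float
    roc_points: np.ndarray
    prc_points: np.ndarray
    threshold: float

    def to_dict(self) -> dict:
        return {
            "counts": dataclasses.asdict(self.counts),
            "threshold": self.threshold,
            **{k: float(v) for k, v in self.scalars.items()},
            "AUROC": float(self.auroc),
            "AUPRC": float(self.auprc),
            "roc_points": self.roc_points.tolist(),
            "prc_points": self.prc_points.tolist(),
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
        return path

    def write_curves(self, roc_path: str | Path, prc_path: str | Path) -> None:
        np.savetxt(
            roc_path, self.roc_points, delimiter="\t", header="fpr\ttpr", comments=""
        )
        np.savetxt(
            prc_path,
            self.prc_points,
            delimiter="\t",
            header="recall\tprecision",
            comments="",
        )


def evaluate_scores(y_true, scores, threshold: float = 0.5) -> MetricsReport:
    """Full evaluation of probability scores at one operating point."""
    c = confusion(y_true, scores, threshold)
    roc_points, auroc = roc(y_true, scores)
    prc_points, auprc = prc(y_true, scores)
    return MetricsReport(
        counts=c,
        scalars=metrics(c),
        auroc=auroc,
        auprc=auprc,
        roc_points=roc_points,
        prc_points=prc_points,
        threshold=threshold,
    )


def plot_curves(report: MetricsReport, roc_png: str | Path, prc_png: str | Path) -> None:
    """Optional ROC/PRC plots (matplotlib, headless backend)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(report.roc_points[:, 0], report.roc_points[:, 1])
    ax.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax.set(xlabel="FPR", ylabel="TPR", title=f"AUROC = {report.auroc:.3f}")
    fig.tight_layout()
    fig.savefig(roc_png, dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(report.prc_points[:, 0], report.prc_points[:, 1])
    ax.set(xlabel="Recall", ylabel="Precision", title=f"AUPRC = {report.auprc:.3f}")
    fig.tight_layout()
    fig.savefig(prc_png, dpi=120)
    plt.close(fig)
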