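"""Confusion-matrix metrics, ROC curves, and trapezoidal AUC.

With confusion counts a (true positives), b (false negatives), c (false
positives) and d (true negatives):

    precision p = a / (a + c)        recall r = a / (a + b)
    accuracy    = (a + d) / (a + b + c + d)
    F1          = 2pr / (p + r) = 2a / (2a + b + c)

Zero-denominator metrics return 0 and are flagged rather than raised, so a
degenerate cross-validation fold cannot abort a sweep. The ROC curve is the
exact step curve of the descending-threshold sweep (a sample is positive at
threshold t iff its score >= t), with sentinels at (0,0) and (1,1); AUC is
its trapezoidal area, which equals the Mann-Whitney probability that a
random case outranks a random control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, NamedTuple, Optional

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "ROCCurve",
    "EvaluationReport",
    "confusion",
    "metrics",
    "roc_curve",
    "auc",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts a=TP, b=FN, c=FP, d=TN."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


class MetricSet(NamedTuple):
    """(precision, recall, accuracy, f1) plus names of zero-denominator metrics."""

    precision: float
    recall: float
    accuracy: float
    f1: float
    degenerate: frozenset = frozenset()


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionMatrix:
    """Tally the 2x2 confusion counts of binary predictions against truth."""
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.shape != truth.shape:
        raise ValueError(
            f"prediction length {pred.shape} does not match truth {truth.shape}"
        )
    return ConfusionMatrix(
        a=int(np.sum((pred == 1) & (truth == 1))),
        b=int(np.sum((pred == 0) & (truth == 1))),
        c=int(np.sum((pred == 1) & (truth == 0))),
        d=int(np.sum((pred == 0) & (truth == 0))),
    )


def metrics(cm: ConfusionMatrix) -> MetricSet:
    """Precision, recall, accuracy and F1 from the confusion counts."""
    degenerate = set()

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            degenerate.add(name)
            return 0.0
        return num / den

    p = ratio(cm.a, cm.a + cm.c, "precision")
    r = ratio(cm.a, cm.a + cm.b, "recall")
    accuracy = ratio(cm.a + cm.d, cm.n, "accuracy")
    f1 = ratio(2 * cm.a, 2 * cm.a + cm.b + cm.c, "f1")
    return MetricSet(p, r, accuracy, f1, frozenset(degenerate))


@dataclass
class ROCCurve:
    """(FPR, TPR) step curve over descending score thresholds."""

    points: list[tuple[float, float]]
    thresholds: list[float]

    def __post_init__(self) -> None:
        if len(self.points) != len(self.thresholds):
            raise ValueError("points and thresholds must be parallel")
        fpr = [p[0] for p in self.points]
        tpr = [p[1] for p in self.points]
        if self.points and (self.points[0] != (0.0, 0.0) or self.points[-1] != (1.0, 1.0)):
            raise ValueError("ROC curve must start at (0,0) and end at (1,1)")
        if np.any(np.diff(fpr) < 0) or np.any(np.diff(tpr) < 0):
            raise ValueError("FPR and TPR must be non-decreasing")


def roc_curve(probabilities: np.ndarray, truth: np.ndarray) -> ROCCurve:
    """Exact threshold-sweep ROC.

    Thresholds are the unique scores in descending order (tied scores give
    one point), preceded by a +inf sentinel for (0, 0); a -inf sentinel
    closes the curve at (1, 1) if the minimum score does not already.
    """
    scores = np.asarray(probabilities, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if not np.all(np.isfinite(scores)):
        raise ValueError("probabilities must be finite")
    n_pos = int(np.sum(truth == 1))
    n_neg = int(np.sum(truth == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes in the truth labels")

    points = [(0.0, 0.0)]
    thresholds = [float("inf")]
    for t in np.unique(scores)[::-1]:
        called = scores >= t
        tpr = np.sum(called & (truth == 1)) / n_pos
        fpr = np.sum(called & (truth == 0)) / n_neg
        points.append((float(fpr), float(tpr)))
        thresholds.append(float(t))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
        thresholds.append(float("-inf"))
    return ROCCurve(points, thresholds)


def auc(curve: ROCCurve) -> float:
    """Trapezoidal area under the ROC step curve, in [0, 1]."""
    fpr = np.array([p[0] for p in curve.points])
    tpr = np.array([p[1] for p in curve.points])
    return float(np.trapezoid(tpr, fpr))


@dataclass
class EvaluationReport:
    """Everything measured on one train/test experiment."""

    confusion: ConfusionMatrix
    precision: float
    recall: float
    accuracy: float
    f1: float
    auc: float
    roc: Optional[ROCCurve] = None
    provenance: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_predictions(
        cls,
        probabilities: np.ndarray,
        pred: np.ndarray,
        truth: np.ndarray,
        provenance: Optional[dict[str, Any]] = None,
    ) -> "EvaluationReport":
        cm = confusion(pred, truth)
        m = metrics(cm)
        curve = roc_curve(probabilities, truth)
        return cls(
            confusion=cm,
            precision=m.precision,
            recall=m.recall,
            accuracy=m.accuracy,
            f1=m.f1,
            auc=auc(curve),
            roc=curve,
            provenance=provenance or {},
        )

    def as_dict(self) -> dict[str, Any]:
        return {
            "a_true_positive": self.confusion.a,
            "b_false_negative": self.confusion.b,
            "c_false_positive": self.confusion.c,
            "d_true_negative": self.confusion.d,
            "precision": self.precision,
            "recall": self.recall,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "auc": self.auc,
        }

    def write(self, directory: str | Path, stem: str = "report") -> dict[str, Path]:
        """Write a flat key-value report and a two-column TSV of ROC points."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        report_path = directory / f"{stem}.txt"
        lines = [f"{k}\t{v}" for k, v in self.as_dict().items()]
        report_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        out = {"report": report_path}
        if self.roc is not None:
            roc_path = directory / f"{stem}_roc.tsv"
            roc_lines = ["fpr\ttpr"] + [
                f"{fpr:.10g}\t{tpr:.10g}" for fpr, tpr in self.roc.points
            ]
            roc_path.write_text("\n".join(roc_lines) + "\n", encoding="utf-8")
            out["roc"] = roc_path
        return out

    def plot_roc(self, path: str | Path) -> Path:
        """Presentation-only ROC plot."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if self.roc is None:
            raise ValueError("report carries no ROC curve")
        fpr = [p[0] for p in self.roc.points]
        tpr = [p[1] for p in self.roc.points]
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot(fpr, tpr, drawstyle="steps-post", label=f"AUC = {self.auc:.3f}")
        ax.plot([0, 1], [0, 1], linestyle="--", color="grey", linewidth=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.legend(loc="lower right")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return Path(path)
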