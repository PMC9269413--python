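"""Classifier evaluation: confusion matrix, accuracy, multiclass ROC, PC1.

Accuracy is the overall fraction correct, (TP+TN)/(TP+FP+TN+FN) in the
one-vs-rest marginalization, which for a multiclass confusion matrix is
simply 100 * trace / total.

ROC analysis is one-vs-rest per class, plus two multiclass averages:

* **micro**: pool every (sample, class) indicator/score pair into one
  binary problem and compute a single curve — each sample contributes
  equally;
* **macro**: interpolate each class's TPR on the pooled FPR grid and
  average the curves — each class contributes equally.

AUCs use the trapezoid rule.

The per-class PC1 representation summarizes one class's spectra by the
first principal axis of its (column-centered) samples x wavelengths
matrix; the explained-variance percentage measures how one-dimensional
the within-class variation is (a multiplicative-gain dominated class is
nearly rank one).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import auc as _auc
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc

from .spectra import SpectrumSet

__all__ = [
    "ConfusionMatrix",
    "ROCReport",
    "ClassifierReport",
    "confusion_matrix",
    "accuracy",
    "roc_curves",
    "classifier_report",
    "pca_class_representation",
]


@dataclass
class ConfusionMatrix:
    """Square count matrix; rows = true labels, columns = predicted."""

    matrix: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=int)
        k = len(self.labels)
        if self.matrix.shape != (k, k):
            raise ValueError(f"matrix shape {self.matrix.shape} != ({k}, {k})")
        if (self.matrix < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def to_dict(self) -> dict:
        return {"labels": list(self.labels), "matrix": self.matrix.tolist()}


def confusion_matrix(
    y_true: Sequence, y_pred: Sequence, labels: Sequence[str]
) -> ConfusionMatrix:
    """Count matrix with entry (i, j) = #(true = labels[i], pred = labels[j])."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    known = set(map(str, labels))
    unknown = {str(v) for v in np.concatenate([y_true, y_pred])} - known
    if unknown:
        raise ValueError(f"labels outside the declared order: {sorted(unknown)}")
    m = _sk_confusion(y_true, y_pred, labels=list(labels))
    return ConfusionMatrix(matrix=m, labels=tuple(map(str, labels)))


def accuracy(cm: ConfusionMatrix) -> float:
    """Overall accuracy in percent: 100 * trace / total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.matrix)) / cm.total


@dataclass
class ROCReport:
    """Per-class, micro- and macro-averaged ROC curves and AUCs."""

    per_class: dict[str, tuple[np.ndarray, np.ndarray, float]]
    micro: tuple[np.ndarray, np.ndarray, float]
    macro: tuple[np.ndarray, np.ndarray, float]
    excluded: tuple[str, ...] = ()

    @property
    def auc_per_class(self) -> dict[str, float]:
        return {k: v[2] for k, v in self.per_class.items()}

    @property
    def micro_auc(self) -> float:
        return self.micro[2]

    @property
    def macro_auc(self) -> float:
        return self.macro[2]

    def to_dict(self) -> dict:
        return {
            "auc_per_class": {k: float(v) for k, v in self.auc_per_class.items()},
            "micro_auc": float(self.micro_auc),
            "macro_auc": float(self.macro_auc),
            "excluded_classes": list(self.excluded),
        }


def roc_curves(
    y_true: Sequence,
    proba: np.ndarray,
    class_order: Sequence[str],
) -> ROCReport:
    """One-vs-rest ROC per class plus micro and macro averages.

    ``proba`` columns follow ``class_order`` and each row must sum to 1
    (tolerance 1e-6).  A class absent from ``y_true`` has an undefined
    one-vs-rest curve; it is excluded from the per-class set and the macro
    average with a warning (its column still participates in the pooled
    micro average as all-negative).
    """
    y_true = np.asarray(y_true)
    proba = np.asarray(proba, dtype=float)
    if proba.ndim != 2 or proba.shape[1] != len(class_order):
        raise ValueError("probability matrix shape does not match class order")
    if proba.shape[0] != y_true.shape[0]:
        raise ValueError("y_true and proba have different sample counts")
    row_sums = proba.sum(axis=1)
    if np.any(np.abs(row_sums - 1.0) > 1e-6):
        raise ValueError("probability rows must sum to 1 (tolerance 1e-6)")
    indicator = np.column_stack([(y_true == c).astype(int) for c in class_order])
    per_class: dict[str, tuple[np.ndarray, np.ndarray, float]] = {}
    excluded = []
    for j, c in enumerate(class_order):
        if indicator[:, j].sum() == 0:
            excluded.append(str(c))
            warnings.warn(
                f"class {c!r} absent from y_true; excluded from per-class/macro ROC",
                stacklevel=2,
            )
            continue
        fpr, tpr, _ = _sk_roc(indicator[:, j], proba[:, j])
        per_class[str(c)] = (fpr, tpr, float(_auc(fpr, tpr)))
    if not per_class:
        raise ValueError("no class present in y_true")
    # micro: pooled (sample, class) pairs
    fpr_mi, tpr_mi, _ = _sk_roc(indicator.ravel(), proba.ravel())
    micro = (fpr_mi, tpr_mi, float(_auc(fpr_mi, tpr_mi)))
    # macro: mean per-class TPR on the pooled FPR grid
    all_fpr = np.unique(np.concatenate([v[0] for v in per_class.values()]))
    mean_tpr = np.zeros_like(all_fpr)
    for fpr, tpr, _ in per_class.values():
        mean_tpr += np.interp(all_fpr, fpr, tpr)
    mean_tpr /= len(per_class)
    macro = (all_fpr, mean_tpr, float(_auc(all_fpr, mean_tpr)))
    return ROCReport(per_class=per_class, micro=micro, macro=macro, excluded=tuple(excluded))


@dataclass
class ClassifierReport:
    """Bundle of the standard held-out evaluation artifacts."""

    confusion: ConfusionMatrix
    accuracy_pct: float
    roc: ROCReport

    def summary(self) -> str:
        lines = [
            f"accuracy: {self.accuracy_pct:.2f}%  (n = {self.confusion.total})",
            f"micro-AUC: {self.roc.micro_auc:.3f}   macro-AUC: {self.roc.macro_auc:.3f}",
            "per-class AUC: "
            + ", ".join(f"{k}={v:.3f}" for k, v in self.roc.auc_per_class.items()),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.to_dict(),
            "accuracy_pct": float(self.accuracy_pct),
            "roc": self.roc.to_dict(),
        }


def classifier_report(
    y_true: Sequence,
    y_pred: Sequence,
    proba: np.ndarray,
    class_order: Sequence[str],
) -> ClassifierReport:
    cm = confusion_matrix(y_true, y_pred, labels=class_order)
    return ClassifierReport(
        confusion=cm,
        accuracy_pct=accuracy(cm),
        roc=roc_curves(y_true, proba, class_order),
    )


def pca_class_representation(
    sset: SpectrumSet, class_label: str
) -> tuple[np.ndarray, float]:
    """First principal axis and explained-variance % of one class's spectra.

    The class's samples x wavelengths matrix is column-mean-centered and
    decomposed by SVD; returns ``(pc1, explained_pct)`` where ``pc1`` is
    the first right singular vector with its sign fixed so its mean is
    non-negative, and ``explained_pct`` = 100 * first eigenvalue / total
    variance.  Requires at least 3 samples of the class on a common grid.
    """
    members = sset.subset(lambda s: s.species == class_label or s.phylum == class_label)
    if len(members) < 3:
        raise ValueError(
            f"PCA needs >= 3 samples of class {class_label!r}, found {len(members)}"
        )
    X = members.reflectance_matrix()
    Xc = X - X.mean(axis=0, keepdims=True)
    _, svals, vt = np.linalg.svd(Xc, full_matrices=False)
    pc1 = vt[0]
    if pc1.mean() < 0:
        pc1 = -pc1
    var = svals**2
    total = float(var.sum())
    if total == 0:
        return pc1, 100.0  # identical samples: degenerate, fully explained
    return pc1, 100.0 * float(var[0]) / total


def plot_roc(report: ROCReport, path, title: str = "ROC curves") -> None:
    """Write a one-panel ROC plot (per-class + micro/macro) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for name, (fpr, tpr, a) in report.per_class.items():
        ax.plot(fpr, tpr, lw=1, label=f"{name} (AUC={a:.2f})")
    ax.plot(*report.micro[:2], "k--", lw=1.5, label=f"micro (AUC={report.micro_auc:.2f})")
    ax.plot(*report.macro[:2], "k:", lw=1.5, label=f"macro (AUC={report.macro_auc:.2f})")
    ax.plot([0, 1], [0, 1], color="0.8", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(title)
    ax.legend(fontsize=7, loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_confusion(cm: ConfusionMatrix, path, title: str = "Confusion matrix") -> None:
    """Write a heatmap of the confusion matrix to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 5))
    im = ax.imshow(cm.matrix, cmap="Blues")
    ax.set_xticks(range(len(cm.labels)), cm.labels, rotation=45, ha="right", fontsize=7)
    ax.set_yticks(range(len(cm.labels)), cm.labels, fontsize=7)
    for i in range(len(cm.labels)):
        for j in range(len(cm.labels)):
            ax.text(j, i, str(cm.matrix[i, j]), ha="center", va="center", fontsize=7)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    ax.set_title(title)
    fig.colorbar(im, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
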