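"""Classifier evaluation: confusion-matrix metrics, one-vs-rest AUC,
bootstrap confidence intervals, and embedding cluster-quality indices.

Aggregates are support-weighted (weighted precision/recall/F1), the
convention used for reporting on imbalanced test sets. Confidence intervals
are non-parametric percentile bootstrap: B with-replacement resamples of the
test set, the metric recomputed on each, and the 2.5th/97.5th percentiles
taken as the interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (
    confusion_matrix as _sk_confusion,
    davies_bouldin_score,
    roc_auc_score,
    silhouette_score,
)

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "confusion",
    "metrics",
    "auc_ovr",
    "bootstrap_ci",
    "cluster_indices",
    "evaluate",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """C x C count matrix; rows are true classes, columns predictions."""

    counts: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "counts", np.asarray(self.counts, dtype=np.int64))
        c = self.counts
        if c.ndim != 2 or c.shape[0] != c.shape[1] or (c < 0).any():
            raise ValueError("confusion matrix must be square and non-negative")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(y_true, y_pred, n_classes: int) -> ConfusionMatrix:
    return ConfusionMatrix(
        _sk_confusion(y_true, y_pred, labels=np.arange(n_classes)))


def metrics(cm: ConfusionMatrix) -> dict:
    """Accuracy plus per-class and support-weighted precision/recall/F1.

    One-vs-rest reduction of the confusion counts; any metric with a zero
    denominator is defined as 0, with a warning.
    """
    c = cm.counts
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(c).astype(np.float64)
    support = c.sum(axis=1).astype(np.float64)  # true-class counts
    predicted = c.sum(axis=0).astype(np.float64)

    def safe_div(num, den, what):
        out = np.zeros_like(num)
        zero = den == 0
        if zero.any():
            warnings.warn(f"{what} undefined for classes {np.flatnonzero(zero)}; "
                          "reported as 0")
        out[~zero] = num[~zero] / den[~zero]
        return out

    precision = safe_div(tp, predicted, "precision")
    recall = safe_div(tp, support, "recall")
    f1 = safe_div(2 * precision * recall, precision + recall, "F1")
    w = support / support.sum()
    return {
        "accuracy": float(tp.sum() / cm.total),
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "weighted_precision": float(w @ precision),
        "weighted_recall": float(w @ recall),
        "weighted_f1": float(w @ f1),
        "support": support.astype(np.int64),
        "errors_per_class": (support - tp).astype(np.int64),
    }


def auc_ovr(scores, labels, n_classes: int | None = None) -> dict:
    """One-vs-rest ROC AUC per class, plus the support-weighted average.

    Equivalent to the normalized Mann-Whitney U statistic with half credit
    for ties. A class absent from the labels has no defined AUC; it is
    reported as NaN and excluded from the weighted mean, with a warning.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    C = n_classes or scores.shape[1]
    per_class = np.full(C, np.nan)
    support = np.bincount(labels, minlength=C).astype(np.float64)
    for c in range(C):
        pos = labels == c
        if not pos.any() or pos.all():
            warnings.warn(f"class {c} absent from one side; AUC undefined")
            continue
        per_class[c] = roc_auc_score(pos.astype(int), scores[:, c])
    ok = ~np.isnan(per_class)
    weighted = float(np.average(per_class[ok], weights=support[ok])) if ok.any() else float("nan")
    return {"per_class": per_class, "weighted": weighted}


def bootstrap_ci(y_true, y_second, metric, B: int = 1000, seed: int = 0,
                 max_retries: int = 100) -> tuple[float, float]:
    """Percentile bootstrap 95% interval for a test-set metric.

    ``metric(y_true_sub, y_second_sub)`` is evaluated on B seeded
    with-replacement resamples of the paired arrays (``y_second`` may hold
    predictions or score rows); the 2.5th and 97.5th percentiles of the B
    statistics are returned. A resample on which the metric raises (e.g. a
    class entirely absent) is redrawn, up to ``max_retries`` times.
    """
    y_true = np.asarray(y_true)
    y_second = np.asarray(y_second)
    n = len(y_true)
    if B < 1 or n == 0:
        raise ValueError("need B >= 1 and a non-empty test set")
    rng = np.random.default_rng(seed)
    stats = np.empty(B)
    for b in range(B):
        for attempt in range(max_retries + 1):
            idx = rng.integers(n, size=n)
            try:
                stats[b] = metric(y_true[idx], y_second[idx])
                break
            except Exception:
                if attempt == max_retries:
                    raise RuntimeError(
                        "metric undefined on every resample attempt")
    return float(np.percentile(stats, 2.5)), float(np.percentile(stats, 97.5))


def cluster_indices(embeddings, labels) -> tuple[float, float]:
    """Silhouette coefficient and Davies-Bouldin index of a labeled embedding.

    Silhouette (Euclidean, mean over points of (b - a)/max(a, b)) approaches
    1 for tight well-separated classes; Davies-Bouldin (mean over classes of
    the worst (s_i + s_j)/d_ij centroid-scatter ratio) approaches 0. A
    singleton class contributes silhouette 0 for its point, with a warning.
    """
    embeddings = np.asarray(embeddings, dtype=np.float64)
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("cluster indices need at least two classes")
    if (counts == 1).any():
        warnings.warn("singleton class present; its silhouette terms are 0")
    return (
        float(silhouette_score(embeddings, labels)),
        float(davies_bouldin_score(embeddings, labels)),
    )


@dataclass
class EvalReport:
    """Everything reported for one model on one test set."""

    confusion: ConfusionMatrix
    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    errors_per_class: np.ndarray
    auc_per_class: np.ndarray = None
    auc_weighted: float = float("nan")
    ci: dict = field(default_factory=dict)
    silhouette: float = float("nan")
    davies_bouldin: float = float("nan")

    def to_dict(self) -> dict:
        out = {
            "confusion": self.confusion.counts.tolist(),
            "accuracy": self.accuracy,
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "weighted_precision": self.weighted_precision,
            "weighted_recall": self.weighted_recall,
            "weighted_f1": self.weighted_f1,
            "errors_per_class": self.errors_per_class.tolist(),
            "auc_weighted": self.auc_weighted,
            "silhouette": self.silhouette,
            "davies_bouldin": self.davies_bouldin,
            "ci": {k: list(v) for k, v in self.ci.items()},
        }
        if self.auc_per_class is not None:
            out["auc_per_class"] = [
                None if np.isnan(a) else a for a in self.auc_per_class]
        return out


def evaluate(y_true, y_pred, n_classes: int, scores=None, embeddings=None,
             bootstrap: int = 0, seed: int = 0) -> EvalReport:
    """One-call evaluation assembling the full report."""
    cm = confusion(y_true, y_pred, n_classes)
    m = metrics(cm)
    report = EvalReport(
        confusion=cm,
        accuracy=m["accuracy"],
        precision=m["precision"],
        recall=m["recall"],
        f1=m["f1"],
        weighted_precision=m["weighted_precision"],
        weighted_recall=m["weighted_recall"],
        weighted_f1=m["weighted_f1"],
        errors_per_class=m["errors_per_class"],
    )
    if scores is not None:
        auc = auc_ovr(scores, y_true, n_classes)
        report.auc_per_class = auc["per_class"]
        report.auc_weighted = auc["weighted"]
    if embeddings is not None:
        report.silhouette, report.davies_bouldin = cluster_indices(
            embeddings, y_true)
    if bootstrap:
        def acc(t, p):
            return metrics(confusion(t, p, n_classes))["accuracy"]

        def wf1(t, p):
            return metrics(confusion(t, p, n_classes))["weighted_f1"]

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report.ci["accuracy"] = bootstrap_ci(
                y_true, y_pred, acc, B=bootstrap, seed=seed)
            report.ci["weighted_f1"] = bootstrap_ci(
                y_true, y_pred, wf1, B=bootstrap, seed=seed)
    return report
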