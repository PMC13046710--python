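"""Confusion counts, classification metrics and cross-validation.

Metrics follow the one-vs-rest count formulation: for class ``k`` the
counts (nTPV, nTNV, nFPV, nFNV) are pooled from the K x K confusion
matrix and

    accuracy  A    = (nTPV + nTNV) / total          (per class, pooled)
    precision PREC = nTPV / (nTPV + nFPV)
    recall    REC  = nTPV / (nTPV + nFNV)
    F1S            = 2 PREC REC / (PREC + REC)

Macro averages are unweighted class means; micro averages pool the
one-vs-rest counts first.  For single-label multiclass data micro
precision = micro recall = overall accuracy (every false positive of
one class is a false negative of another), which is why a paper can
legitimately print identical "accuracy" and "recall" while a
different "precision" signals a macro average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = ["ConfusionCounts", "MetricReport", "CVSummary", "confusion",
           "metrics", "cross_validate"]


@dataclass(frozen=True)
class ConfusionCounts:
    """K x K confusion matrix (rows true, columns predicted) plus the
    per-class one-vs-rest decomposition."""

    matrix: np.ndarray
    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    @property
    def n_classes(self) -> int:
        return self.matrix.shape[0]

    @property
    def total(self) -> int:
        return int(self.matrix.sum())


def confusion(y_true, y_pred, n_classes: int) -> ConfusionCounts:
    """Count the confusion matrix and its one-vs-rest decomposition."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences must have equal length")
    if y_true.size and (y_true.min() < 0 or y_true.max() >= n_classes
                        or y_pred.min() < 0 or y_pred.max() >= n_classes):
        raise ValueError(f"labels out of range [0, {n_classes})")
    m = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(m, (y_true, y_pred), 1)
    tp = np.diag(m).copy()
    fp = m.sum(axis=0) - tp
    fn = m.sum(axis=1) - tp
    tn = m.sum() - tp - fp - fn
    return ConfusionCounts(matrix=m, tp=tp, tn=tn, fp=fp, fn=fn)


def _safe_div(num, den, what: str):
    num, den = np.asarray(num, dtype=float), np.asarray(den, dtype=float)
    bad = den == 0
    if np.any(bad):
        warnings.warn(f"zero denominator in {what}; reporting 0",
                      stacklevel=3)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(bad, 0.0, num / np.maximum(den, 1e-300))
    return out


@dataclass(frozen=True)
class MetricReport:
    accuracy: float
    precision_per_class: np.ndarray
    recall_per_class: np.ndarray
    f1_per_class: np.ndarray
    precision_macro: float
    recall_macro: float
    f1_macro: float
    precision_micro: float
    recall_micro: float

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision_per_class": self.precision_per_class.tolist(),
            "recall_per_class": self.recall_per_class.tolist(),
            "f1_per_class": self.f1_per_class.tolist(),
            "precision_macro": self.precision_macro,
            "recall_macro": self.recall_macro,
            "f1_macro": self.f1_macro,
            "precision_micro": self.precision_micro,
            "recall_micro": self.recall_micro,
        }


def metrics(cc: ConfusionCounts) -> MetricReport:
    """Per-class, macro and micro metrics from confusion counts."""
    if cc.total == 0:
        raise ValueError("empty confusion counts")
    prec = _safe_div(cc.tp, cc.tp + cc.fp, "precision")
    rec = _safe_div(cc.tp, cc.tp + cc.fn, "recall")
    f1 = _safe_div(2 * prec * rec, prec + rec, "F1")
    acc = float(cc.tp.sum()) / cc.total
    tp, fp, fn = cc.tp.sum(), cc.fp.sum(), cc.fn.sum()
    return MetricReport(
        accuracy=acc,
        precision_per_class=prec, recall_per_class=rec, f1_per_class=f1,
        precision_macro=float(prec.mean()), recall_macro=float(rec.mean()),
        f1_macro=float(f1.mean()),
        precision_micro=float(_safe_div(tp, tp + fp, "micro precision")),
        recall_micro=float(_safe_div(tp, tp + fn, "micro recall")),
    )


@dataclass(frozen=True)
class CVSummary:
    k: int
    fold_scores: tuple[float, ...]
    mean: float
    std: float
    ci_low: float
    ci_high: float


def summarize_folds(fold_scores, clip: tuple[float, float] | None = (0.0, 1.0)
                    ) -> CVSummary:
    """Mean, sample std and normal-approximation 95% CI of fold scores."""
    scores = np.asarray(fold_scores, dtype=float)
    k = scores.size
    mean = float(scores.mean())
    std = float(scores.std(ddof=1)) if k > 1 else 0.0
    half = 1.96 * std / np.sqrt(k)
    lo, hi = mean - half, mean + half
    if clip is not None:
        lo, hi = max(lo, clip[0]), min(hi, clip[1])
    return CVSummary(k=k, fold_scores=tuple(scores.tolist()), mean=mean,
                     std=std, ci_low=float(lo), ci_high=float(hi))


def cross_validate(fit_score, labels, k: int = 5, seed: int = 0) -> CVSummary:
    """Stratified k-fold accuracy summary.

    ``fit_score(train_idx, test_idx) -> accuracy`` runs one fold of the
    caller's pipeline; this function owns only the fold geometry and
    the statistics.  Every sample lands in exactly one validation fold.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = np.bincount(labels)
    if counts[counts > 0].min() < k:
        raise ValueError("every class needs at least k members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = [float(fit_score(tr, te))
              for tr, te in skf.split(np.zeros(labels.size), labels)]
    return summarize_folds(scores)
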