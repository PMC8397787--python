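"""Multiclass evaluation: confusion matrix, macro metrics, AUC with DeLong CI.

For C = 5 classes, per-class one-vs-rest counts TP_i, FP_i, FN_i, TN_i are
read off the confusion matrix and give

    sensitivity_i = TP_i / (TP_i + FN_i)
    specificity_i = TN_i / (TN_i + FP_i)
    precision_i   = TP_i / (TP_i + FP_i)

The reported macro metrics are the unweighted means over classes, and the F1
is the harmonic mean of the *macro* sensitivity and macro precision:

    F1 = 2 * SE_macro * Pr_macro / (SE_macro + Pr_macro)

(note: this is not the mean of per-class F1 scores; the two differ).

Per-class discrimination is summarized by the one-vs-rest AUC of the class
probability (Mann-Whitney statistic, half credit for ties), with 95%
confidence intervals from the DeLong structural-components variance
estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata

from .model import N_CLASSES

__all__ = [
    "ConfusionMatrix",
    "MacroMetrics",
    "AucResult",
    "confusion_matrix",
    "per_class_rates",
    "macro_metrics",
    "ovr_auc",
    "delong_ci",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """C x C counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(counts < 0):
            raise ValueError("confusion matrix counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def ovr_counts(self, class_index: int) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) of class ``class_index`` against the rest."""
        c = self.counts
        tp = int(c[class_index, class_index])
        fp = int(c[:, class_index].sum() - tp)
        fn = int(c[class_index, :].sum() - tp)
        tn = int(c.sum() - tp - fp - fn)
        return tp, fp, fn, tn


@dataclass(frozen=True)
class MacroMetrics:
    """Macro-averaged metrics plus the per-class rates they average."""

    se_macro: float
    sp_macro: float
    pr_macro: float
    f1: float
    per_class: tuple  # C x (sensitivity, specificity, precision)
    undefined_flags: tuple = ()  # class indices with a 0/0 rate reported as 0


@dataclass(frozen=True)
class AucResult:
    """One-vs-rest AUC with its DeLong confidence interval."""

    auc: float
    ci_low: float
    ci_high: float
    class_index: int
    level: float = 0.95


def confusion_matrix(
    true_labels, predicted_labels, n_classes: int = N_CLASSES
) -> ConfusionMatrix:
    """Tally counts[t][p] = number of cases with true t predicted p."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError(f"label arrays differ in length: {t.shape} vs {p.shape}")
    if t.size and (t.min() < 0 or t.max() >= n_classes or p.min() < 0 or p.max() >= n_classes):
        raise ValueError(f"labels must be in [0, {n_classes})")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts=counts)


def _safe_ratio(num: int, den: int) -> tuple[float, bool]:
    """num/den, with the 0/0 case reported as 0.0 plus an 'undefined' flag."""
    if den == 0:
        return 0.0, True
    return num / den, False


def per_class_rates(
    cm: ConfusionMatrix, class_index: int
) -> tuple[float, float, float]:
    """(sensitivity, specificity, precision) of one class vs the rest.

    A rate whose denominator is zero (class absent from truth and/or
    predictions) is reported as 0.0; :func:`macro_metrics` records which
    classes were affected.
    """
    tp, fp, fn, tn = cm.ovr_counts(class_index)
    se, _ = _safe_ratio(tp, tp + fn)
    sp, _ = _safe_ratio(tn, tn + fp)
    pr, _ = _safe_ratio(tp, tp + fp)
    return se, sp, pr


def macro_metrics(cm: ConfusionMatrix) -> MacroMetrics:
    """Unweighted per-class means, plus F1 of the macro SE and macro Pr."""
    per_class = []
    flags = []
    for i in range(cm.n_classes):
        tp, fp, fn, tn = cm.ovr_counts(i)
        se, f1_ = _safe_ratio(tp, tp + fn)
        sp, f2_ = _safe_ratio(tn, tn + fp)
        pr, f3_ = _safe_ratio(tp, tp + fp)
        per_class.append((se, sp, pr))
        if f1_ or f2_ or f3_:
            flags.append(i)
    arr = np.asarray(per_class)
    se_macro = float(arr[:, 0].mean())
    sp_macro = float(arr[:, 1].mean())
    pr_macro = float(arr[:, 2].mean())
    if se_macro + pr_macro > 0:
        f1 = 2.0 * se_macro * pr_macro / (se_macro + pr_macro)
    else:
        f1 = 0.0
    return MacroMetrics(
        se_macro=se_macro,
        sp_macro=sp_macro,
        pr_macro=pr_macro,
        f1=f1,
        per_class=tuple(per_class),
        undefined_flags=tuple(flags),
    )


def _binary_labels(true_labels, class_index: int) -> np.ndarray:
    y = np.asarray(true_labels, dtype=np.int64)
    return (y == class_index).astype(np.int64)


def ovr_auc(scores, true_labels, class_index: int) -> float:
    """One-vs-rest AUC of the class-``class_index`` probability.

    Computed as the normalized Mann-Whitney statistic on the class
    probability, with half credit for ties.  ``scores`` is (n, C) class
    probabilities (or any monotone score; only column ``class_index`` is
    used).  Requires at least one positive and one negative case.
    """
    s = np.asarray(scores, dtype=np.float64)
    x = s[:, class_index] if s.ndim == 2 else s
    y = _binary_labels(true_labels, class_index)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"class {class_index} is degenerate: {n_pos} positive / {n_neg} negative cases"
        )
    ranks = rankdata(x)  # midranks give the tie convention automatically
    rank_sum_pos = ranks[y == 1].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _delong_components(x_pos: np.ndarray, x_neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong structural components via midranks (fast O(n log n) form)."""
    m, n = x_pos.size, x_neg.size
    all_scores = np.concatenate([x_pos, x_neg])
    r_all = rankdata(all_scores)
    r_pos = rankdata(x_pos)
    r_neg = rankdata(x_neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[:m] - r_pos) / n  # per-positive placement values
    v01 = 1.0 - (r_all[m:] - r_neg) / m  # per-negative placement values
    return v10, v01, float(auc)


def delong_ci(
    scores, true_labels, class_index: int, level: float = 0.95
) -> AucResult:
    """AUC with an asymptotic confidence interval by the DeLong method.

    The variance is the structural-components estimator
    ``var(V10)/m + var(V01)/n`` (sample variances over the m positives and n
    negatives); the CI is ``auc +- z * sqrt(var)`` clipped to [0, 1].  With
    perfect separation the variance collapses to 0 and a degenerate interval
    ``[auc, auc]`` is returned with a warning.
    """
    s = np.asarray(scores, dtype=np.float64)
    x = s[:, class_index] if s.ndim == 2 else s
    y = _binary_labels(true_labels, class_index)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError(
            f"class {class_index} is degenerate: needs >= 1 positive and >= 1 negative"
        )
    x_pos = x[y == 1]
    x_neg = x[y == 0]
    v10, v01, auc = _delong_components(x_pos, x_neg)
    m, n = x_pos.size, x_neg.size
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    if var <= 0:
        warnings.warn(
            f"DeLong variance is zero for class {class_index} (perfect separation); "
            "returning a degenerate confidence interval",
            stacklevel=2,
        )
        return AucResult(auc=auc, ci_low=auc, ci_high=auc, class_index=class_index, level=level)
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return AucResult(
        auc=auc,
        ci_low=float(np.clip(auc - half, 0.0, 1.0)),
        ci_high=float(np.clip(auc + half, 0.0, 1.0)),
        class_index=class_index,
        level=level,
    )
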