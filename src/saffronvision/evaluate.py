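"""Performance analysis: confusion matrices, per-class rates, ROC/AUC,
and ANOVA with Duncan's multiple range grouping of classifier accuracies.

Per-class rates follow the recall/precision convention expressed in
percent: TP rate = per-class recall, FN = 100 - TP, PP rate = per-class
precision, FD = 100 - PP. Multiclass ROC is one-vs-rest per class; the
overall AUC of a classifier is the unweighted mean of its per-class AUCs.

Duncan's test orders the group means and compares each stretch of r
adjacent means against a critical range built from the studentized-range
quantile at the protection level 1 - (1 - alpha)^(r - 1); stretches inside
an already-declared-homogeneous stretch are not tested (the bridging rule).
Groups that share a letter are not significantly different.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "CLASS_ORDER",
    "ConfusionMatrix",
    "RateTable",
    "DuncanResult",
    "confusion",
    "class_rates",
    "roc_auc",
    "anova_oneway",
    "duncan_groups",
]

#: Fixed class order used throughout reports.
CLASS_ORDER = ("Pushal", "Negin", "Sargol")


@dataclass
class ConfusionMatrix:
    """C x C counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    classes: tuple[str, ...]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total)


@dataclass
class RateTable:
    """Per-class TP/FN/PP/FD rates in percent (NaN where undefined)."""

    classes: tuple[str, ...]
    tp_rate: np.ndarray
    fn_rate: np.ndarray
    pp_rate: np.ndarray
    fd_rate: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tp_rate": self.tp_rate, "fn_rate": self.fn_rate,
             "pp_rate": self.pp_rate, "fd_rate": self.fd_rate},
            index=list(self.classes),
        )


@dataclass
class DuncanResult:
    """Homogeneous-subset grouping of ordered means."""

    names: list[str]           # sorted by mean, descending
    means: np.ndarray          # sorted descending
    letters: list[str]         # letter display, aligned with names
    alpha: float
    error_mean_square: float
    df_within: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.means, "group": self.letters}, index=self.names)


def confusion(true_labels, predicted_labels, classes=None) -> ConfusionMatrix:
    """Confusion matrix with a fixed class order (default: the grade order)."""
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("label vectors must have equal length")
    if classes is None:
        classes = [c for c in CLASS_ORDER if c in set(true_labels) | set(predicted_labels)]
        if not classes:
            classes = sorted(set(true_labels) | set(predicted_labels))
    unknown = (set(true_labels) | set(predicted_labels)) - set(classes)
    if unknown:
        raise ValueError(f"unknown labels {sorted(map(str, unknown))}")
    counts = _sk_confusion(true_labels, predicted_labels, labels=list(classes))
    return ConfusionMatrix(counts=counts, classes=tuple(classes))


def class_rates(cm: ConfusionMatrix) -> RateTable:
    """TP/FN/PP/FD percentages from a confusion matrix.

    TP + FN = 100 and PP + FD = 100 hold per class by construction. A class
    with no true samples (no prediction) has undefined TP/FN (PP/FD),
    reported as NaN with a warning.
    """
    counts = cm.counts.astype(np.float64)
    diag = np.diag(counts)
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tp = 100.0 * diag / row
        pp = 100.0 * diag / col
    if np.any(row == 0) or np.any(col == 0):
        warnings.warn("class with no true samples or no predictions: rates reported as NaN")
        tp = np.where(row == 0, np.nan, tp)
        pp = np.where(col == 0, np.nan, pp)
    return RateTable(
        classes=cm.classes, tp_rate=tp, fn_rate=100.0 - tp,
        pp_rate=pp, fd_rate=100.0 - pp,
    )


def roc_auc(scores, labels, positive_class) -> tuple[pd.DataFrame, float]:
    """One-vs-rest ROC curve and its trapezoid AUC.

    Ties in the scores are handled so the AUC equals the concordance
    probability P(score+ > score-) + 0.5 P(score+ = score-).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    y = (labels == positive_class).astype(int)
    if y.min() == y.max():
        raise ValueError("need both positive and negative samples")
    fpr, tpr, thr = _sk_roc_curve(y, scores)
    auc = float(np.trapezoid(tpr, fpr))
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return curve, auc


def anova_oneway(groups: dict[str, np.ndarray] | list[np.ndarray]):
    """Classical one-way ANOVA from explicit sums of squares.

    Returns ``(F, df_between, df_within, error_mean_square, p)``. With zero
    within-group variance and equal means, F is undefined (NaN).
    """
    if isinstance(groups, dict):
        arrays = [np.asarray(g, dtype=np.float64) for g in groups.values()]
    else:
        arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least two observations")
    all_values = np.concatenate(arrays)
    grand = all_values.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = len(arrays) - 1
    df_within = all_values.size - len(arrays)
    ms_between = ss_between / df_between
    ems = ss_within / df_within
    if ems == 0.0:
        if ms_between == 0.0:
            warnings.warn("degenerate ANOVA: zero variance everywhere; F undefined")
            return np.nan, df_between, df_within, 0.0, np.nan
        return np.inf, df_between, df_within, 0.0, 0.0
    F = ms_between / ems
    p = float(stats.f.sf(F, df_between, df_within))
    return float(F), df_between, df_within, float(ems), p


@lru_cache(maxsize=4096)
def _duncan_quantile(alpha: float, r: int, df: int) -> float:
    """Studentized-range quantile at Duncan's protection level 1-(1-a)^(r-1)."""
    return float(stats.studentized_range.ppf((1.0 - alpha) ** (r - 1), r, df))


def duncan_groups(
    means: dict[str, float],
    n_per_group: int,
    error_mean_square: float,
    df_within: int,
    alpha: float = 0.05,
) -> DuncanResult:
    """Duncan's multiple range test on balanced group means.

    The critical range for a stretch of ``r`` adjacent ordered means is
    ``q_duncan(r, df) * sqrt(EMS / n)``; the stepwise procedure tests
    stretches from the widest down and never tests inside a stretch already
    declared homogeneous. The letter display assigns one letter per maximal
    homogeneous stretch.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2 (balanced design)")
    if error_mean_square < 0 or df_within < 1:
        raise ValueError("invalid ANOVA error term")
    names = sorted(means, key=lambda k: -means[k])
    m = np.array([means[k] for k in names], dtype=np.float64)
    k = len(m)
    if k < 2:
        raise ValueError("need at least two groups")
    se = np.sqrt(error_mean_square / n_per_group)

    # nonsignificant[i][j]: the stretch i..j (inclusive) is homogeneous
    homogeneous = np.zeros((k, k), dtype=bool)
    if se == 0.0:
        for i in range(k):
            for j in range(i, k):
                homogeneous[i, j] = np.allclose(m[i], m[j])
    else:
        # widest stretches first; bridging rule skips covered stretches
        for span in range(k, 1, -1):
            crit = _duncan_quantile(alpha, span, df_within) * se
            for i in range(0, k - span + 1):
                j = i + span - 1
                covered = any(
                    homogeneous[a, b]
                    for a in range(0, i + 1)
                    for b in range(j, k)
                    if (b - a) > (j - i)
                )
                if covered:
                    homogeneous[i, j] = True
                elif m[i] - m[j] <= crit:
                    homogeneous[i, j] = True
        for i in range(k):
            homogeneous[i, i] = True

    # maximal homogeneous stretches -> letters
    stretches = []
    for i in range(k):
        j = i
        while j + 1 < k and homogeneous[i, j + 1]:
            j += 1
        stretches.append((i, j))
    maximal = []
    for s in stretches:
        if not any(o[0] <= s[0] and s[1] <= o[1] and o != s for o in stretches):
            if s not in maximal:
                maximal.append(s)
    letters = ["" for _ in range(k)]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for li, (i, j) in enumerate(sorted(maximal)):
        ch = alphabet[li % len(alphabet)]
        for idx in range(i, j + 1):
            letters[idx] += ch
    return DuncanResult(
        names=names, means=m, letters=letters, alpha=alpha,
        error_mean_square=float(error_mean_square), df_within=int(df_within),
    )
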