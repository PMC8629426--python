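"""Rank-based group comparison, rank correlation, and ROC/Youden thresholding.

The Wilcoxon rank-sum test is exact (full enumeration over rank assignments,
tie-aware) for small pooled samples and uses the tie-corrected normal
approximation with continuity correction otherwise. ROC analysis scans every
distinct-score midpoint plus +/- infinity with the orientation
"higher score => predicted responder", and picks the operating threshold by
maximizing Youden's J = sensitivity + specificity - 1 (ties resolved toward
the smallest threshold, favoring sensitivity).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "EXACT_ENUMERATION_MAX_N",
    "ConfusionMetrics",
    "RocResult",
    "wilcoxon_rank_sum",
    "spearman",
    "roc_with_youden",
    "confusion_metrics",
]

#: Largest pooled sample size for which the exact rank-sum p is enumerated.
EXACT_ENUMERATION_MAX_N = 12


def wilcoxon_rank_sum(
    x, y, two_tailed: bool = True
) -> tuple[float, float]:
    """Wilcoxon rank-sum test for a location shift between two samples.

    Returns (W, p) where W is the mid-rank sum of ``x``. For pooled size
    n_x + n_y <= 12 the p-value is exact: all C(N, n_x) assignments of the
    pooled ranks are enumerated and assignments with |W' - E[W]| >= |W - E[W]|
    are counted (two-tailed) or with W' >= W (one-tailed, ``x`` larger).
    Larger samples use the tie-corrected normal approximation with continuity
    correction. Identical pooled values give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx == 0 or ny == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # mid-ranks for ties
    w = float(ranks[:nx].sum())
    n = nx + ny
    e_w = nx * (n + 1) / 2.0

    if n <= EXACT_ENUMERATION_MAX_N:
        dev = abs(w - e_w)
        count = 0
        total = 0
        for idx in combinations(range(n), nx):
            w_c = ranks[list(idx)].sum()
            if two_tailed:
                count += abs(w_c - e_w) >= dev - 1e-12
            else:
                count += w_c >= w - 1e-12
            total += 1
        return w, count / total

    # tie-corrected normal approximation
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_w = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_w <= 0:
        return w, 1.0  # all pooled values identical
    if two_tailed:
        z = (abs(w - e_w) - 0.5) / math.sqrt(var_w)
        p = 2.0 * sps.norm.sf(max(z, 0.0))
    else:
        z = (w - e_w - 0.5) / math.sqrt(var_w)
        p = float(sps.norm.sf(z))
    return w, min(float(p), 1.0)


def spearman(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks).

    Raises ValueError when either argument has zero rank variance (the
    correlation is undefined, not 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length 1-D arrays with >= 2 values")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("spearman undefined: an argument has zero rank variance")
    rho = sps.spearmanr(x, y).statistic
    return float(rho)


@dataclass(frozen=True)
class ConfusionMetrics:
    """Standard binary-classification ratios; NaN marks an undefined ratio."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float


def _ratio(num: float, den: float, name: str, warn: bool = True) -> float:
    if den == 0:
        if warn:
            warnings.warn(f"{name} undefined (zero denominator)", stacklevel=3)
        return math.nan
    return num / den


def confusion_metrics(tp: int, fp: int, tn: int, fn: int, warn: bool = True) -> ConfusionMetrics:
    """Sensitivity, specificity, PPV, NPV, accuracy from confusion counts.

    Undefined ratios (zero denominator) are returned as NaN with a warning,
    never silently as 0.
    """
    counts = (tp, fp, tn, fn)
    if any(c < 0 or c != int(c) for c in counts):
        raise ValueError("counts must be nonnegative integers")
    total = sum(counts)
    if total == 0:
        raise ValueError("at least one count must be positive")
    return ConfusionMetrics(
        sensitivity=_ratio(tp, tp + fn, "sensitivity", warn),
        specificity=_ratio(tn, tn + fp, "specificity", warn),
        ppv=_ratio(tp, tp + fp, "ppv", warn),
        npv=_ratio(tn, tn + fn, "npv", warn),
        accuracy=(tp + tn) / total,
    )


@dataclass(frozen=True)
class RocResult:
    """Full ROC scan plus the Youden-optimal operating point."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_threshold: float
    youden_j: float
    metrics: ConfusionMetrics  # at the Youden threshold


def roc_with_youden(scores, labels) -> RocResult:
    """ROC analysis with 'higher score = predicted responder' orientation.

    ``labels`` are booleans with favorable (responder) = positive. Thresholds
    are all midpoints between distinct sorted scores plus -inf and +inf;
    prediction is positive iff score >= threshold. The Youden threshold
    maximizes J = sens + spec - 1, ties going to the smallest threshold.
    AUC is the trapezoidal area, which equals the Mann-Whitney U statistic
    normalized by n_pos * n_neg.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be matching 1-D arrays")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    distinct = np.unique(scores)
    midpoints = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], midpoints, [np.inf]))

    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, thr in enumerate(thresholds):
        pred = scores >= thr
        tp = int(np.sum(pred & labels))
        tn = int(np.sum(~pred & ~labels))
        sens[i] = tp / n_pos
        spec[i] = tn / n_neg

    j = sens + spec - 1.0
    best = int(np.argmax(j))  # thresholds ascending -> first max = smallest
    thr = float(thresholds[best])
    pred = scores >= thr
    tp = int(np.sum(pred & labels))
    fp = int(np.sum(pred & ~labels))
    tn = int(np.sum(~pred & ~labels))
    fn = int(np.sum(~pred & labels))

    # integrate along the ROC path (threshold decreasing: (0,0) -> (1,1));
    # sorting by FPR would scramble vertical segments
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))

    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        youden_threshold=thr,
        youden_j=float(j[best]),
        metrics=confusion_metrics(tp, fp, tn, fn, warn=False),
    )
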