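"""ROC / confusion evaluation machinery.

Binary AUC is the tie-corrected Mann-Whitney rank statistic; its confidence
interval uses the DeLong variance estimate by default, with a seeded
bootstrap alternative.  Multiclass evaluation is one-vs-rest with macro
(unweighted mean over classes present) and micro (pooled one-hot expansion)
averaging.  Operating metrics (TPR, TNR, PPV, NPV, accuracy, F1) are
reported at the threshold maximizing the Youden index J = TPR + TNR - 1,
with "predicted positive if score >= threshold" and ties resolved to the
lowest such threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import norm, rankdata

from .categories import CategoryMap

__all__ = [
    "binary_auc",
    "auc_ci",
    "multiclass_auc",
    "confusion",
    "youden_metrics",
    "roc_curve_points",
    "YoudenReport",
    "MulticlassAucReport",
]


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(bool)
    if labels.all() or (~labels).all():
        raise ValueError("both classes must be present")
    return labels


def binary_auc(scores, labels, sample_weight=None) -> float:
    """Mann-Whitney AUC with tie correction.

    With ``sample_weight`` the statistic generalizes to weighted concordant
    pair counting (ties counted half).
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    if sample_weight is None:
        r = rankdata(scores)
        n_pos = int(labels.sum())
        n_neg = labels.size - n_pos
        return float((r[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
    w = np.asarray(sample_weight, dtype=float)
    order = np.argsort(scores, kind="mergesort")
    s, y, w = scores[order], labels[order], w[order]
    w_pos, w_neg = w * y, w * (~y)
    cum_neg = np.concatenate([[0.0], np.cumsum(w_neg)])
    total = 0.0
    i = 0
    n = s.size
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            j += 1
        tie_neg = w_neg[i:j].sum()
        pos_here = w_pos[i:j].sum()
        total += pos_here * (cum_neg[i] + 0.5 * tie_neg)
        i = j
    return float(total / (w_pos.sum() * w_neg.sum()))


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance via structural components."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = pos.size, neg.size
    # placement values using midranks
    all_r = rankdata(np.concatenate([pos, neg]))
    r_pos = rankdata(pos)
    r_neg = rankdata(neg)
    v10 = (all_r[:m] - r_pos) / n  # per-positive components
    v01 = 1.0 - (all_r[m:] - r_neg) / m  # per-negative components
    auc = v10.mean()
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def auc_ci(
    scores,
    labels,
    method: str = "delong",
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """95% (by default) confidence interval for the AUC, clipped to [0, 1].

    ``delong``: normal approximation with the DeLong variance estimate.
    ``bootstrap``: seeded stratified percentile bootstrap.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("need at least 2 members per class")
    if method == "delong":
        auc, var = _delong_variance(scores, labels)
        if var == 0.0 and auc in (0.0, 1.0):
            warnings.warn("degenerate AUC with zero variance; interval clipped")
        z = norm.ppf(0.5 + level / 2)
        half = z * np.sqrt(var)
        return (float(np.clip(auc - half, 0, 1)), float(np.clip(auc + half, 0, 1)))
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        ipos = np.nonzero(labels)[0]
        ineg = np.nonzero(~labels)[0]
        stats = np.empty(n_boot)
        for b in range(n_boot):
            idx = np.concatenate(
                [rng.choice(ipos, ipos.size), rng.choice(ineg, ineg.size)]
            )
            stats[b] = binary_auc(scores[idx], labels[idx])
        lo, hi = np.percentile(stats, [100 * (0.5 - level / 2), 100 * (0.5 + level / 2)])
        return float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1))
    raise ValueError(f"unknown CI method {method!r}")


@dataclass
class MulticlassAucReport:
    per_class: dict
    macro: float
    micro: float
    absent_classes: list


def multiclass_auc(prob_matrix, labels, classes) -> MulticlassAucReport:
    """One-vs-rest AUC per class plus macro / micro averages.

    ``prob_matrix`` rows must lie on the simplex over ``classes``.  Classes
    absent from ``labels`` are excluded from the macro average and listed in
    the report.
    """
    P = np.asarray(prob_matrix, dtype=float)
    labels = np.asarray(labels)
    classes = np.asarray(classes)
    if P.shape != (labels.size, classes.size):
        raise ValueError("prob_matrix shape must be (n_samples, n_classes)")
    if np.any(P < -1e-9) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("probability rows must lie on the simplex")
    per_class = {}
    absent = []
    for j, c in enumerate(classes):
        mask = labels == c
        if mask.all() or not mask.any():
            absent.append(c)
            continue
        per_class[c] = binary_auc(P[:, j], mask)
    macro = float(np.mean(list(per_class.values()))) if per_class else np.nan
    onehot = (labels[:, None] == classes[None, :]).astype(float)
    micro = binary_auc(P.ravel(), onehot.ravel())
    return MulticlassAucReport(per_class, macro, micro, absent)


def confusion(pred, truth, cmap: CategoryMap):
    """Aggregated confusion matrix (rows = truth) and per-category TPR."""
    import pandas as pd

    p = cmap(pred)
    t = cmap(truth)
    k = len(cmap.labels)
    mat = np.zeros((k, k), dtype=int)
    np.add.at(mat, (t, p), 1)
    df = pd.DataFrame(mat, index=list(cmap.labels), columns=list(cmap.labels))
    with np.errstate(invalid="ignore", divide="ignore"):
        tpr = np.where(mat.sum(axis=1) > 0, np.diag(mat) / mat.sum(axis=1), np.nan)
    tpr_s = pd.Series(tpr, index=list(cmap.labels), name="tpr")
    return df, tpr_s


@dataclass
class YoudenReport:
    threshold: float
    youden_j: float
    tpr: float
    tnr: float
    ppv: float
    npv: float
    accuracy: float
    f1: float


def youden_metrics(scores, labels) -> YoudenReport:
    """Operating metrics at the Youden-optimal threshold.

    The threshold maximizing J = TPR + TNR - 1 is searched over all observed
    score values (classification rule: positive if score >= threshold);
    among ties the lowest threshold wins.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    n_pos = labels.sum()
    n_neg = labels.size - n_pos
    # descending unique thresholds: tp/fp counts by cumulative sums
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    tp_cum = np.cumsum(y)
    fp_cum = np.cumsum(~y)
    last = np.nonzero(np.diff(s) != 0)[0]
    idx = np.concatenate([last, [s.size - 1]])  # last index of each tie group
    thr = s[idx]
    tpr = tp_cum[idx] / n_pos
    fpr = fp_cum[idx] / n_neg
    j = tpr - fpr
    jmax = j.max()
    # ties in J: lowest threshold = latest in descending order
    best = np.nonzero(j == jmax)[0][-1]
    t = float(thr[best])
    pred = scores >= t
    tp = int((pred & labels).sum())
    fp = int((pred & ~labels).sum())
    fn = int((~pred & labels).sum())
    tn = int((~pred & ~labels).sum())
    tpr_v = tp / n_pos
    tnr_v = tn / n_neg
    ppv = tp / (tp + fp) if tp + fp else np.nan
    npv = tn / (tn + fn) if tn + fn else np.nan
    acc = (tp + tn) / labels.size
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else np.nan
    return YoudenReport(t, float(tpr_v + tnr_v - 1), float(tpr_v), float(tnr_v),
                        float(ppv), float(npv), float(acc), float(f1))


def roc_curve_points(scores, labels) -> "np.ndarray":
    """(FPR, TPR, threshold) triples over descending thresholds."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    tp = np.cumsum(y)
    fp = np.cumsum(~y)
    last = np.nonzero(np.diff(s) != 0)[0]
    idx = np.concatenate([last, [s.size - 1]])
    out = np.column_stack(
        [fp[idx] / (~labels).sum(), tp[idx] / labels.sum(), s[idx]]
    )
    return np.vstack([[0.0, 0.0, np.inf], out])
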