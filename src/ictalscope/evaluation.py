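"""Segment-level performance statistics.

Confusion counts from thresholded seizure probabilities, the four standard
binary-classification metrics

    sensitivity = TP / (TP + FN)
    specificity = TN / (FP + TN)
    accuracy    = (TP + TN) / (TP + FN + FP + TN)
    F1          = 2 TP / (2 TP + FP + FN)

ROC/AUC, a paired permutation test for the difference between two ROC
curves, and mean +/- SE aggregation over repeated training runs. Counts may
be non-integer means over runs; metric values reported alongside published
tables are truncated (not rounded) to 3 decimals, which is the convention
the reference results follow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "ROCResult",
    "confusion",
    "metrics",
    "roc_auc",
    "permutation_test_auc",
    "aggregate_runs",
    "anova_oneway_f",
    "truncate3",
]


def truncate3(x: float) -> float:
    """Truncate toward zero to 3 decimals (table display convention)."""
    return math.trunc(x * 1000) / 1000


@dataclass
class ConfusionCounts:
    """TP/FP/TN/FN; floats allowed (means over repeated runs)."""

    tp: float
    fp: float
    tn: float
    fn: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    sensitivity: float
    specificity: float
    accuracy: float
    f1: float
    undefined: tuple[str, ...] = ()

    def truncated(self) -> dict:
        return {
            k: truncate3(getattr(self, k))
            for k in ("accuracy", "sensitivity", "specificity", "f1")
            if not math.isnan(getattr(self, k))
        }


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def confusion(scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> ConfusionCounts:
    """Counts from thresholding p_seizure >= threshold against 0/1 labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.size == 0:
        raise ValueError("empty input")
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=float(np.sum(pred & pos)),
        fp=float(np.sum(pred & ~pos)),
        tn=float(np.sum(~pred & ~pos)),
        fn=float(np.sum(~pred & pos)),
    )


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """The four metric formulas; zero denominators yield NaN + a flag."""
    undef = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            undef.append(name)
            return float("nan")
        return num / den

    rep = MetricsReport(
        sensitivity=ratio(counts.tp, counts.tp + counts.fn, "sensitivity"),
        specificity=ratio(counts.tn, counts.fp + counts.tn, "specificity"),
        accuracy=ratio(counts.tp + counts.tn, counts.total, "accuracy"),
        f1=ratio(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn, "f1"),
    )
    rep.undefined = tuple(undef)
    return rep


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """ROC curve and trapezoidal AUC.

    The AUC equals the pairwise probability that a random positive outscores
    a random negative, counting ties as 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present to compute a ROC curve")
    fpr, tpr, thr = roc_curve(labels, scores)
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(np.trapezoid(tpr, fpr)))


def _auc_rank(scores: np.ndarray, pos_mask: np.ndarray) -> float:
    """Mann-Whitney AUC (midranks handle ties); used in the permutation loop."""
    r = stats.rankdata(scores)
    n_pos = int(pos_mask.sum())
    n_neg = pos_mask.size - n_pos
    return (r[pos_mask].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def permutation_test_auc(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Paired permutation test for the AUC difference of two classifiers.

    Both score vectors must refer to the same segments in the same order.
    The observed statistic is |AUC_A - AUC_B|; the null distribution swaps
    the (a_i, b_i) pair of each segment independently with probability 1/2,
    which preserves the per-segment score pool while destroying any
    systematic classifier difference. p = (1 + #{null >= observed}) /
    (1 + n_perm).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not (a.shape == b.shape == labels.shape):
        raise ValueError("scores_a, scores_b and labels must have equal length")
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present")
    pos = labels == 1
    observed = abs(_auc_rank(a, pos) - _auc_rank(b, pos))

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    swap = rng.random((n_perm, a.size)) < 0.5
    A = np.where(swap, b, a)
    B = np.where(swap, a, b)
    rA = stats.rankdata(A, axis=1)
    rB = stats.rankdata(B, axis=1)
    n_pos = int(pos.sum())
    n_neg = pos.size - n_pos
    aucA = (rA[:, pos].sum(axis=1) - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    aucB = (rB[:, pos].sum(axis=1) - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    null = np.abs(aucA - aucB)
    return float((1 + np.sum(null >= observed - 1e-12)) / (1 + n_perm))


def aggregate_runs(runs: list[ConfusionCounts]) -> dict:
    """Per-cell mean and standard error (SD/sqrt(n)) over repeated runs."""
    if not runs:
        raise ValueError("no runs to aggregate")
    out = {}
    n = len(runs)
    for cell in ("tp", "fp", "tn", "fn"):
        vals = np.array([getattr(r, cell) for r in runs], dtype=float)
        se = float(vals.std(ddof=1) / np.sqrt(n)) if n >= 2 else float("nan")
        out[cell] = {"mean": float(vals.mean()), "se": se}
    out["n_runs"] = n
    return out


def anova_oneway_f(groups: list[np.ndarray]) -> tuple[float, float]:
    """Textbook one-way ANOVA F statistic and p-value across groups.

    Convenience for comparing FP/FN counts across classifier families; the
    per-run counts are also exported as CSV for external stats packages.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    k = len(groups)
    ns = np.array([g.size for g in groups])
    grand = np.concatenate(groups).mean()
    ss_between = float(sum(n * (g.mean() - grand) ** 2 for n, g in zip(ns, groups)))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    df_b, df_w = k - 1, int(ns.sum()) - k
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return F, p
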