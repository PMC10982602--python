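"""Diagnostic-evaluation statistics for index-based classification.

Contingency metrics with Wald confidence intervals, Cohen's kappa,
empirical ROC curves with midrank-tie AUC, Youden-optimal cutoffs, DeLong
confidence intervals for the AUC, and leave-one-out cross-validation of a
cutoff-based classifier.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: Score orientations: "greater" means high scores indicate disease
#: (PSP-style rules), "less" means low scores do (MSA-style rules).
DIRECTIONS = ("greater", "less")


@dataclass
class ProportionEstimate:
    """A proportion with a Wald confidence interval clipped to [0, 1]."""

    value: float
    lower: float
    upper: float
    n: int


@dataclass
class ContingencyTable:
    """2x2 counts for one disease-vs-others dichotomy."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"count {name} must be non-negative")
        if self.total == 0:
            raise ValueError("contingency table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class RocResult:
    """Empirical ROC curve with AUC and the score orientation used."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    direction: str
    auc_ci: tuple[float, float] | None = None
    optimal_cutoff: float | None = None
    youden_j: float | None = None


@dataclass
class CvResult:
    """Pooled held-out performance of per-fold re-estimated cutoffs."""

    accuracy: float
    kappa: float
    per_fold_cutoffs: np.ndarray
    predictions: np.ndarray
    n_excluded_folds: int = 0


def _wald_interval(p: float, m: int, ci_level: float) -> tuple[float, float]:
    z = sps.norm.ppf(0.5 + ci_level / 2.0)
    half = z * math.sqrt(p * (1.0 - p) / m)
    return max(0.0, p - half), min(1.0, p + half)


def contingency_metrics(
    table: ContingencyTable,
    ci_level: float = 0.95,
) -> dict[str, ProportionEstimate | None]:
    """Sensitivity, specificity and accuracy with Wald intervals.

    A metric whose denominator is zero is reported as ``None`` (undefined)
    rather than raising.
    """
    if not (0 < ci_level < 1):
        raise ValueError("ci_level must be in (0, 1)")
    out: dict[str, ProportionEstimate | None] = {}
    pairs = {
        "sensitivity": (table.tp, table.tp + table.fn),
        "specificity": (table.tn, table.tn + table.fp),
        "accuracy": (table.tp + table.tn, table.total),
    }
    for name, (num, den) in pairs.items():
        if den == 0:
            out[name] = None
            continue
        p = num / den
        lo, hi = _wald_interval(p, den, ci_level)
        out[name] = ProportionEstimate(p, lo, hi, den)
    return out


def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Chance-corrected agreement between two label vectors.

    kappa = (p_o - p_e) / (1 - p_e), with expected agreement p_e from the
    product of marginal label frequencies. In the degenerate case where both
    raters use a single identical category (p_e = p_o = 1), kappa is 1.
    """
    a = np.asarray(labels_a, dtype=object)
    b = np.asarray(labels_b, dtype=object)
    if a.shape != b.shape:
        raise ValueError(f"label vectors differ in length: {a.size} vs {b.size}")
    if a.size < 2:
        raise ValueError("need at least 2 observations")
    n = a.size
    cats = sorted(set(a) | set(b), key=str)
    p_o = float(np.mean(a == b))
    p_e = sum(
        float(np.mean(a == c)) * float(np.mean(b == c)) for c in cats
    )
    if p_e >= 1.0:
        return 1.0 if p_o >= 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def _orient(scores: np.ndarray, direction: str) -> np.ndarray:
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    return scores if direction == "greater" else -scores


def _auc_midrank(oriented: np.ndarray, truth: np.ndarray) -> float:
    """Concordance-probability AUC via midranks (ties count one half)."""
    pos = oriented[truth]
    neg = oriented[~truth]
    ranks = sps.rankdata(oriented)
    r_pos = ranks[truth].sum()
    n1, n0 = pos.size, neg.size
    return (r_pos - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def roc_curve(
    scores: Sequence[float],
    truth: Sequence[bool],
    direction: str = "greater",
) -> RocResult:
    """Empirical ROC over midpoint thresholds between distinct scores.

    ``truth`` is the disease indicator. Thresholds are the midpoints between
    consecutive distinct oriented scores, plus -inf/+inf sentinels, and a
    subject is called diseased when its oriented score is >= the threshold
    (for ``direction="less"`` the reported thresholds are on the original
    scale and the call is score <= threshold). The AUC uses the midrank
    convention, so it equals the two-sample concordance probability.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth differ in length")
    if truth.all() or (~truth).all():
        raise ValueError("both classes must be present")
    oriented = _orient(scores, direction)

    distinct = np.unique(oriented)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thr = np.concatenate(([-np.inf], mids, [np.inf]))
    # predictions: oriented >= t -> disease
    pred = oriented[None, :] >= thr[:, None]
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    sens = (pred & truth[None, :]).sum(axis=1) / n_pos
    spec = ((~pred) & (~truth)[None, :]).sum(axis=1) / n_neg
    auc = _auc_midrank(oriented, truth)
    if direction == "less":
        thr = -thr
    return RocResult(thr, sens, spec, float(auc), direction)


def youden_cutoff(roc: RocResult) -> tuple[float, float]:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Ties in J are broken toward higher sensitivity, then toward the cutoff
    with smaller absolute value (a deterministic, scale-symmetric rule).
    """
    j = roc.sensitivity + roc.specificity - 1.0
    if j.size == 0:
        raise ValueError("empty ROC")
    best = np.flatnonzero(j == j.max())
    if best.size > 1:
        sens_best = roc.sensitivity[best]
        best = best[sens_best == sens_best.max()]
    if best.size > 1:
        finite = np.abs(np.nan_to_num(roc.thresholds[best], posinf=np.inf, neginf=np.inf))
        best = best[np.argsort(finite, kind="stable")][:1]
    i = int(best[0])
    return float(roc.thresholds[i]), float(j[i])


def delong_auc_ci(
    scores: Sequence[float],
    truth: Sequence[bool],
    level: float = 0.95,
    direction: str = "greater",
) -> tuple[float, tuple[float, float], bool]:
    """AUC with DeLong's variance-based confidence interval.

    Returns ``(auc, (lower, upper), degenerate)``. The variance comes from
    the empirical variances of the placement values of each class; the
    normal-approximation interval is clipped to [0, 1]. With perfectly
    separated samples the variance collapses to 0 and the interval
    degenerates to a point, flagged via ``degenerate=True``.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if truth.sum() < 2 or (~truth).sum() < 2:
        raise ValueError("DeLong CI requires >= 2 members in each class")
    oriented = _orient(scores, direction)
    x = oriented[truth]
    y = oriented[~truth]
    m, n = x.size, y.size
    # Placement values via the pairwise Heaviside kernel (psi = 1, 1/2, 0).
    diff = x[:, None] - y[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    auc = float(psi.mean())
    s10 = v10.var(ddof=1)
    s01 = v01.var(ddof=1)
    var = s10 / m + s01 / n
    degenerate = var <= 0
    if degenerate:
        logger.warning("DeLong variance is zero (perfect separation); interval collapses")
        return auc, (auc, auc), True
    z = sps.norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(var)
    return auc, (max(0.0, auc - half), min(1.0, auc + half)), False


def _best_cutoff(scores: np.ndarray, truth: np.ndarray, direction: str) -> float:
    roc = roc_curve(scores, truth, direction)
    cutoff, _ = youden_cutoff(roc)
    return cutoff


def _predict(scores: np.ndarray, cutoff: float, direction: str) -> np.ndarray:
    if direction == "greater":
        return scores >= cutoff
    return scores <= cutoff


def loocv_evaluate(
    scores: Sequence[float],
    truth: Sequence[bool],
    direction: str = "greater",
    fixed_cutoff: float | None = None,
) -> CvResult:
    """Leave-one-out validation of the Youden-cutoff classifier.

    For each held-out subject the optimal cutoff is re-estimated on the
    remaining n-1 subjects (unless ``fixed_cutoff`` is given, in which case
    the same cutoff is applied in every fold) and the held-out subject is
    classified. Accuracy and Cohen's kappa are computed on the pooled
    held-out predictions. A training fold that loses one class entirely is
    excluded with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    n = scores.size
    if n < 3:
        raise ValueError("LOOCV requires n >= 3")
    if truth.all() or (~truth).all():
        raise ValueError("both classes must be present")
    preds = np.zeros(n, dtype=bool)
    used = np.ones(n, dtype=bool)
    cutoffs = np.full(n, np.nan)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        t_train = truth[keep]
        if t_train.all() or (~t_train).all():
            logger.warning("fold %d: training set lost one class; excluded", i)
            used[i] = False
            continue
        cut = fixed_cutoff if fixed_cutoff is not None else _best_cutoff(
            scores[keep], t_train, direction
        )
        cutoffs[i] = cut
        preds[i] = _predict(scores[i : i + 1], cut, direction)[0]
    if not used.any():
        raise ValueError("all LOOCV folds were degenerate")
    acc = float(np.mean(preds[used] == truth[used]))
    kap = cohens_kappa(preds[used].astype(int), truth[used].astype(int))
    return CvResult(acc, kap, cutoffs[used], preds[used], int((~used).sum()))


def evaluate_index(
    scores: Sequence[float],
    truth: Sequence[bool],
    direction: str,
    ci_level: float = 0.95,
    loocv: bool = True,
) -> dict:
    """Full ROC + Youden + DeLong (+ optional LOOCV) report for one contrast."""
    roc = roc_curve(scores, truth, direction)
    cutoff, j = youden_cutoff(roc)
    auc, ci, degenerate = delong_auc_ci(scores, truth, ci_level, direction)
    roc.auc_ci = ci
    roc.optimal_cutoff = cutoff
    roc.youden_j = j
    report = {
        "auc": roc.auc,
        "auc_ci": list(ci),
        "auc_ci_degenerate": degenerate,
        "optimal_cutoff": cutoff,
        "youden_j": j,
        "direction": direction,
    }
    if loocv:
        cv = loocv_evaluate(scores, truth, direction)
        report["loocv_accuracy"] = cv.accuracy
        report["loocv_kappa"] = cv.kappa
    return report


def pairwise_roi_tests(
    values: Sequence[float],
    groups: Sequence[str],
) -> list[dict]:
    """Pairwise Mann-Whitney U tests between groups, Bonferroni-corrected.

    Convenience report for comparing ROI z-scores across diagnostic groups;
    the correction spans all pairwise contrasts of the given ROI's values.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    names = sorted(set(groups), key=str)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    out = []
    for a, b in pairs:
        va, vb = values[groups == a], values[groups == b]
        stat, p = sps.mannwhitneyu(va, vb, alternative="two-sided")
        out.append(
            {"group_a": a, "group_b": b, "u": float(stat), "p_raw": float(p),
             "p_bonferroni": min(1.0, float(p) * len(pairs))}
        )
    return out
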