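"""ROC and precision-recall analysis for two-group biomarker discrimination.

AUC is the Mann-Whitney U statistic (ties half-credited), its standard
error the Hanley-McNeil closed form, confidence intervals the normal
approximation clipped to [0, 1].  Paired AUC comparison uses the
placement-value (DeLong) covariance inside the Hanley-McNeil z framework;
precision-recall curves are re-expressed at an arbitrary population
prevalence via PPV = rho*TPR / (rho*TPR + (1-rho)*FPR) with a seeded
stratified bootstrap for the AUPRC interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ROCResult",
    "PRResult",
    "auc_mann_whitney",
    "hanley_mcneil_se",
    "auc_confidence_interval",
    "compare_auc",
    "pr_with_prevalence",
]


@dataclass(frozen=True)
class ROCResult:
    """AUC with Hanley-McNeil standard error and the ROC staircase."""

    auc: float
    se: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    orientation: str
    points: np.ndarray  # (m, 2) array of (fpr, tpr), staircase from (0,0) to (1,1)
    q1: float = field(default=0.0)
    q2: float = field(default=0.0)


@dataclass(frozen=True)
class PRResult:
    """Prevalence-adjusted precision-recall curve and its area."""

    prevalence: float
    points: np.ndarray  # (m, 2) array of (recall, ppv)
    auprc: float
    ci_low: float
    ci_high: float
    degenerate: bool = False


def _auc_value(pos: np.ndarray, neg: np.ndarray) -> float:
    """Tie-half-credited pairwise concordance, computed from midranks."""
    n1, n2 = pos.size, neg.size
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


def _staircase(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(pos.size, dtype=bool), np.zeros(neg.size, dtype=bool)])
    # thresholds: each distinct observed score plus sentinels; predict positive for score >= t
    order = np.argsort(-scores, kind="mergesort")
    scores, labels = scores[order], labels[order]
    distinct = np.r_[True, np.diff(scores) != 0]
    tp = np.cumsum(labels)
    fp = np.cumsum(~labels)
    cut = np.flatnonzero(np.r_[distinct[1:], True])  # last index of each tied block
    tpr = np.r_[0.0, tp[cut] / pos.size]
    fpr = np.r_[0.0, fp[cut] / neg.size]
    return np.column_stack([fpr, tpr])


def auc_mann_whitney(pos, neg, orientation: str = "higher_is_positive") -> ROCResult:
    """ROC AUC for positive-group vs negative-group scores.

    ``orientation`` is one of "higher_is_positive", "lower_is_positive" or
    "auto" (flip so that AUC >= 0.5, recording which direction was used).
    The returned result carries the staircase, the Hanley-McNeil SE and the
    95% normal CI.
    """
    pos = np.asarray(pos, dtype=float).ravel()
    neg = np.asarray(neg, dtype=float).ravel()
    pos, neg = pos[np.isfinite(pos)], neg[np.isfinite(neg)]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must be non-empty")

    if orientation == "auto":
        orientation = "higher_is_positive" if _auc_value(pos, neg) >= 0.5 else "lower_is_positive"
    if orientation == "lower_is_positive":
        pos_o, neg_o = -pos, -neg
    elif orientation == "higher_is_positive":
        pos_o, neg_o = pos, neg
    else:
        raise ValueError(f"unknown orientation {orientation!r}")

    auc = _auc_value(pos_o, neg_o)
    se = hanley_mcneil_se(auc, pos.size, neg.size)
    ci_low, ci_high = _normal_ci(auc, se, 0.95)
    return ROCResult(
        auc=auc,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        n_pos=pos.size,
        n_neg=neg.size,
        orientation=orientation,
        points=_staircase(pos_o, neg_o),
        q1=auc / (2.0 - auc),
        q2=2.0 * auc**2 / (1.0 + auc),
    )


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil standard error of an AUC.

    ``se^2 = (A(1-A) + (n1-1)(Q1-A^2) + (n2-1)(Q2-A^2)) / (n1 n2)`` with
    ``Q1 = A/(2-A)`` and ``Q2 = 2A^2/(1+A)``.
    """
    if not 0.0 <= auc <= 1.0:
        raise ValueError("auc must be in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("group sizes must be >= 1")
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1.0 - auc) + (n_pos - 1) * (q1 - auc**2) + (n_neg - 1) * (q2 - auc**2)) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def _normal_ci(a: float, se: float, level: float) -> tuple[float, float]:
    z = stats.norm.ppf(0.5 + level / 2.0)
    return float(np.clip(a - z * se, 0.0, 1.0)), float(np.clip(a + z * se, 0.0, 1.0))


def auc_confidence_interval(roc: ROCResult, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation CI ``A +- z se`` clipped to [0, 1]."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    return _normal_ci(roc.auc, roc.se, level)


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject placement values: V10_i = P(score_i > neg) + ties/2, V01_j likewise."""
    diff = pos[:, None] - neg[None, :]
    mat = (diff > 0).astype(float) + 0.5 * (diff == 0)
    return mat.mean(axis=1), mat.mean(axis=0)


def compare_auc(roc_a: ROCResult, roc_b: ROCResult, paired: bool = False, scores=None) -> tuple[float, float]:
    """Two-sided z test for a difference between two AUCs.

    Unpaired: ``z = (A1-A2)/sqrt(se1^2 + se2^2)``.  Paired (both markers on
    the same subjects) additionally needs ``scores = (pos_a, neg_a, pos_b,
    neg_b)`` and subtracts twice the placement-value covariance estimated
    DeLong-style.
    """
    diff = roc_a.auc - roc_b.auc
    if not paired:
        denom = np.sqrt(roc_a.se**2 + roc_b.se**2)
    else:
        if scores is None:
            raise ValueError("paired comparison requires the raw per-subject scores")
        pos_a, neg_a, pos_b, neg_b = (np.asarray(s, dtype=float).ravel() for s in scores)
        if pos_a.size != pos_b.size or neg_a.size != neg_b.size:
            raise ValueError("paired comparison needs identical subjects for both markers")
        v10_a, v01_a = _placements(pos_a, neg_a)
        v10_b, v01_b = _placements(pos_b, neg_b)
        n1, n2 = pos_a.size, neg_a.size
        cov = 0.0
        if n1 > 1:
            cov += float(np.cov(v10_a, v10_b, ddof=1)[0, 1]) / n1
        if n2 > 1:
            cov += float(np.cov(v01_a, v01_b, ddof=1)[0, 1]) / n2
        var = roc_a.se**2 + roc_b.se**2 - 2.0 * cov
        denom = np.sqrt(max(var, 0.0))
    if denom == 0.0:
        return 0.0, 1.0
    z = diff / denom
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def _pr_points(points: np.ndarray, rho: float) -> np.ndarray:
    fpr, tpr = points[:, 0], points[:, 1]
    denom = rho * tpr + (1.0 - rho) * fpr
    with np.errstate(invalid="ignore", divide="ignore"):
        ppv = np.where(denom > 0, rho * tpr / denom, 1.0)
    return np.column_stack([tpr, ppv])  # recall nondecreasing along staircase


def _auprc(pr: np.ndarray) -> float:
    recall, ppv = pr[:, 0], pr[:, 1]
    return float(np.trapezoid(ppv, recall))


def pr_with_prevalence(
    roc: ROCResult,
    prevalence: float,
    n_boot: int = 200,
    seed: int | None = 0,
    scores=None,
    level: float = 0.95,
) -> PRResult:
    """Precision-recall curve re-expressed at a population prevalence.

    At every ROC operating point, ``PPV = rho TPR / (rho TPR + (1-rho) FPR)``;
    AUPRC integrates PPV over recall by trapezoid.  The CI comes from a
    seeded stratified bootstrap of the underlying scores (``scores = (pos,
    neg)``; omit for a point estimate only).  A degenerate all-tie ROC
    yields AUPRC = rho, flagged.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be in (0, 1)")
    pts = roc.points
    degenerate = pts.shape[0] <= 2  # only the sentinel corners: no usable thresholds
    if degenerate:
        pr = np.array([[0.0, prevalence], [1.0, prevalence]])
        auprc = prevalence
    else:
        pr = _pr_points(pts, prevalence)
        auprc = _auprc(pr)
    ci_low = ci_high = float("nan")
    if scores is not None and n_boot > 0:
        pos = np.asarray(scores[0], dtype=float).ravel()
        neg = np.asarray(scores[1], dtype=float).ravel()
        rng = np.random.default_rng(seed)
        vals = np.empty(n_boot)
        for b in range(n_boot):
            pb = rng.choice(pos, size=pos.size, replace=True)
            nb = rng.choice(neg, size=neg.size, replace=True)
            if np.all(pb == pb[0]) and np.all(nb == nb[0]) and pb[0] == nb[0]:
                vals[b] = prevalence
                continue
            orientation = roc.orientation
            stair = _staircase(-pb, -nb) if orientation == "lower_is_positive" else _staircase(pb, nb)
            vals[b] = _auprc(_pr_points(stair, prevalence))
        lo, hi = np.percentile(vals, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
        ci_low, ci_high = float(lo), float(hi)
    return PRResult(prevalence, pr, auprc, ci_low, ci_high, degenerate)
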