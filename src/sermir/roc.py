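"""Empirical ROC curves, AUC and confidence intervals.

AUC is the tie-corrected concordance probability (Mann-Whitney): the
probability that a randomly chosen case scores above a randomly chosen
control, ties counting one half.  Curves enumerate every distinct score
as a threshold under the decision rule ``score > threshold -> case``, so
the trapezoidal area equals the pairwise AUC identically.

Confidence intervals are normal-approximation intervals on the AUC with
either the DeLong (1988) variance from placement values (default,
tie-robust) or the Hanley-McNeil (1982) variance (the classic formula
most legacy clinical software reports), clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class RocResult:
    comparison: str
    auc: float
    ci: tuple[float, float]
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    n_case: int
    n_control: int
    flipped: bool = False
    ci_method: str = "delong"
    flags: list[str] = field(default_factory=list)


def _split(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    case = scores[labels == 1]
    control = scores[labels == 0]
    if case.size == 0 or control.size == 0:
        raise ValueError("both classes must be nonempty")
    return case, control


def auc(scores, labels) -> float:
    """Mann-Whitney AUC with tie correction, via mid-ranks.

    Equals (1/(n1*n0)) * sum over case-control pairs of
    1[case > control] + 0.5 * 1[case == control].
    """
    case, control = _split(scores, labels)
    n1, n0 = case.size, control.size
    ranks = stats.rankdata(np.concatenate([case, control]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _placements(case: np.ndarray, control: np.ndarray):
    """DeLong structural components: per-case and per-control placement
    values (fraction of the other class strictly below, ties half)."""
    # V10[i] = P_hat(control < case_i) + 0.5 P_hat(control == case_i)
    order = np.sort(control)
    lo = np.searchsorted(order, case, side="left")
    hi = np.searchsorted(order, case, side="right")
    v10 = (lo + 0.5 * (hi - lo)) / control.size
    order = np.sort(case)
    lo = np.searchsorted(order, control, side="left")
    hi = np.searchsorted(order, control, side="right")
    v01 = 1.0 - (lo + 0.5 * (hi - lo)) / case.size
    return v10, v01


def delong_variance(scores, labels) -> float:
    case, control = _split(scores, labels)
    v10, v01 = _placements(case, control)
    s10 = v10.var(ddof=1) if case.size > 1 else 0.0
    s01 = v01.var(ddof=1) if control.size > 1 else 0.0
    return float(s10 / case.size + s01 / control.size)


def hanley_mcneil_variance(scores, labels) -> float:
    case, control = _split(scores, labels)
    a = auc(scores, labels)
    n1, n0 = case.size, control.size
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1 - a) + (n1 - 1) * (q1 - a * a) + (n0 - 1) * (q2 - a * a)) / (n1 * n0)
    return float(max(var, 0.0))


def auc_ci(scores, labels, level: float = 0.95, method: str = "delong"):
    """Normal-approximation CI for the AUC, clipped to [0, 1].

    A degenerate variance (e.g. AUC exactly 1 under DeLong) collapses
    the interval to the point estimate and flags the result.
    """
    case, control = _split(scores, labels)
    if case.size < 2 or control.size < 2:
        raise ValueError("need at least two samples per class for a CI")
    a = auc(scores, labels)
    if method == "delong":
        var = delong_variance(scores, labels)
    elif method == "hanley":
        var = hanley_mcneil_variance(scores, labels)
    else:
        raise ValueError(f"unknown CI method {method!r}")
    flags = []
    if var <= 0:
        flags.append("DEGENERATE_CI")
        lo = hi = a
    else:
        z = stats.norm.ppf(0.5 + level / 2.0)
        half = z * np.sqrt(var)
        lo, hi = max(0.0, a - half), min(1.0, a + half)
    return (float(lo), float(hi)), flags


def roc_curve(scores, labels):
    """(fpr, tpr, thresholds) at every distinct score plus +/-inf
    sentinels, decision rule score > threshold; runs (0,0) -> (1,1)."""
    case, control = _split(scores, labels)
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    thr = np.concatenate([[np.inf], np.unique(scores)[::-1], [-np.inf]])
    tpr = np.empty(thr.size)
    fpr = np.empty(thr.size)
    for i, t in enumerate(thr):
        tpr[i] = np.mean(case > t)
        fpr[i] = np.mean(control > t)
    # drop thresholds that do not move the operating point
    keep = np.ones(thr.size, dtype=bool)
    keep[1:] = (np.diff(fpr) != 0) | (np.diff(tpr) != 0)
    return fpr[keep], tpr[keep], thr[keep]


def orient_scores(scores, labels):
    """Negate scores when raw AUC < 0.5 so reported AUC is always >= 0.5
    (the down-regulated-marker convention); returns (scores, flipped)."""
    scores = np.asarray(scores, dtype=float)
    if auc(scores, labels) < 0.5:
        return -scores, True
    return scores, False


def roc_analysis(
    scores,
    labels,
    comparison: str = "",
    level: float = 0.95,
    ci_method: str = "delong",
    orient: bool = True,
) -> RocResult:
    """Full ROC evaluation: orientation, curve, AUC and CI."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    flipped = False
    if orient:
        scores, flipped = orient_scores(scores, labels)
    fpr, tpr, thr = roc_curve(scores, labels)
    a = auc(scores, labels)
    ci, flags = auc_ci(scores, labels, level=level, method=ci_method)
    return RocResult(
        comparison=comparison,
        auc=a,
        ci=ci,
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        n_case=int((labels == 1).sum()),
        n_control=int((labels == 0).sum()),
        flipped=flipped,
        ci_method=ci_method,
        flags=flags,
    )
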