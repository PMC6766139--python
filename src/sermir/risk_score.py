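"""Reference-interval risk score with logistic-regression weights.

The panel classifier works in three steps, all fitted on the training
set only and then frozen:

1. Per miRNA, a *reference interval* threshold is taken from the control
   group: the 95th percentile of control expression for an up-regulated
   miRNA, the 5th percentile for a down-regulated one.  Percentiles use
   linear interpolation between order statistics (position 1+(n-1)p).
2. Each sample's expression is binarized against the threshold:
   s = 1 when expression exceeds the upper bound (UP) or falls below the
   lower bound (DOWN), strictly; ties and MISSING values score 0.
3. Each miRNA's weight W_j is the slope of a univariate logistic
   regression of disease status on s_j (fitted by Newton-Raphson; for a
   binary predictor without separation this is exactly the log odds
   ratio of the 2x2 table).  The per-sample risk score is the weighted
   sum RSF_i = sum_j W_j * s_ij.

Complete separation (a zero cell in the s-by-label 2x2 table) makes the
logistic MLE infinite; the weight then falls back to the
Haldane-Anscombe correction (add 0.5 to all four cells) and is flagged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datamodel import Direction, ExpressionMatrix

log = logging.getLogger(__name__)

MIN_CONTROLS_FOR_PERCENTILE = 20


@dataclass
class WeightFit:
    weight: float
    separation: bool = False
    degenerate: bool = False


@dataclass
class RiskModel:
    """Frozen per-miRNA direction, control-percentile threshold and
    logistic weight."""

    assays: list[str]
    directions: dict[str, Direction]
    thresholds: dict[str, float]
    weights: dict[str, float]
    flags: dict[str, list[str]] = field(default_factory=dict)
    down_rule: str = "below_lower"

    def to_json(self, path=None) -> str:
        payload = {
            "assays": self.assays,
            "directions": {a: d.value for a, d in self.directions.items()},
            "thresholds": self.thresholds,
            "weights": self.weights,
            "flags": self.flags,
            "down_rule": self.down_rule,
        }
        text = json.dumps(payload, indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path) -> "RiskModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            assays=payload["assays"],
            directions={a: Direction(d) for a, d in payload["directions"].items()},
            thresholds=payload["thresholds"],
            weights=payload["weights"],
            flags=payload.get("flags", {}),
            down_rule=payload.get("down_rule", "below_lower"),
        )


@dataclass
class RiskScoreResult:
    s: pd.DataFrame  # samples x assays, entries in {0, 1}
    rsf: pd.Series  # per-sample weighted sum


def reference_threshold(control_values, direction: Direction) -> float:
    """95th (UP) or 5th (DOWN) percentile of finite control expressions,
    by linear interpolation between closest order statistics."""
    vals = np.asarray(control_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("empty control values: cannot form a reference interval")
    if vals.size < MIN_CONTROLS_FOR_PERCENTILE:
        log.warning(
            "reference interval from only %d controls; percentile unstable", vals.size
        )
    p = 95.0 if direction is Direction.UP else 5.0
    return float(np.percentile(vals, p, method="linear"))


def binarize(x: float, threshold: float, direction: Direction, down_rule: str = "below_lower") -> int:
    """Score one expression value against a reference-interval bound.

    UP: s = 1 iff x > threshold (strictly).  DOWN with the default
    ``below_lower`` rule: s = 1 iff x < threshold.  The alternative
    ``above_lower`` rule (s = 1 iff x > threshold, i.e. above the lower
    bound) is selectable for sensitivity analysis but scores nearly
    every sample and is not recommended.  MISSING (NaN) scores 0.
    """
    if not np.isfinite(x):
        log.debug("MISSING expression scored as s=0")
        return 0
    if direction is Direction.UP:
        return int(x > threshold)
    if down_rule == "below_lower":
        return int(x < threshold)
    if down_rule == "above_lower":
        return int(x > threshold)
    raise ValueError(f"unknown down_rule {down_rule!r}")


def binarize_array(x: np.ndarray, threshold: float, direction: Direction, down_rule: str = "below_lower") -> np.ndarray:
    """Vectorized :func:`binarize`; NaN scores 0."""
    x = np.asarray(x, dtype=float)
    if direction is Direction.UP or (direction is Direction.DOWN and down_rule == "above_lower"):
        s = x > threshold
    elif down_rule == "below_lower":
        s = x < threshold
    else:
        raise ValueError(f"unknown down_rule {down_rule!r}")
    return np.where(np.isfinite(x), s.astype(int), 0)


def _logor_corrected(n11: float, n10: float, n01: float, n00: float) -> float:
    return float(np.log(((n11 + 0.5) * (n00 + 0.5)) / ((n10 + 0.5) * (n01 + 0.5))))


def fit_weight(s: np.ndarray, labels: np.ndarray, tol: float = 1e-10) -> WeightFit:
    """Univariate logistic regression of case/control label on a binary
    risk score; returns the slope coefficient.

    ``labels``: 1 = case, 0 = control.  A constant s carries no
    information: weight 0 with a DEGENERATE flag.  On separation the
    Haldane-Anscombe corrected log odds ratio is returned with a
    SEPARATION flag.
    """
    s = np.asarray(s, dtype=float)
    y = np.asarray(labels, dtype=float)
    if s.shape != y.shape:
        raise ValueError("s and labels must have equal length")
    if not (np.isin(s, (0, 1)).all() and np.isin(y, (0, 1)).all()):
        raise ValueError("s and labels must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both classes must be present in labels")
    if s.min() == s.max():
        return WeightFit(0.0, degenerate=True)
    n11 = float(((s == 1) & (y == 1)).sum())  # cases with s=1
    n10 = float(((s == 0) & (y == 1)).sum())
    n01 = float(((s == 1) & (y == 0)).sum())
    n00 = float(((s == 0) & (y == 0)).sum())
    if min(n11, n10, n01, n00) == 0:
        return WeightFit(_logor_corrected(n11, n10, n01, n00), separation=True)
    x = sm.add_constant(s)
    fit = sm.Logit(y, x).fit(method="newton", tol=tol, disp=0)
    return WeightFit(float(fit.params[1]))


def risk_score(s_i, weights) -> float:
    """RSF_i = sum_j W_j * s_ij (exact weighted sum)."""
    s_i = np.asarray(s_i, dtype=float)
    w = np.asarray(weights, dtype=float)
    if s_i.shape != w.shape:
        raise ValueError("score vector and weight vector lengths differ")
    return float(np.dot(w, s_i))


def determine_directions(
    expr: ExpressionMatrix, case_ids, control_ids, assays=None
) -> dict[str, Direction]:
    """Direction per miRNA from training group means: case mean above
    control mean means UP."""
    assays = list(assays) if assays is not None else expr.assay_ids
    out = {}
    for a in assays:
        case_mean = expr.expression.loc[list(case_ids), a].mean(skipna=True)
        ctrl_mean = expr.expression.loc[list(control_ids), a].mean(skipna=True)
        out[a] = Direction.UP if case_mean > ctrl_mean else Direction.DOWN
    return out


def build_risk_model(
    expr: ExpressionMatrix,
    case_ids,
    control_ids,
    directions: dict[str, Direction] | None = None,
    assays=None,
    down_rule: str = "below_lower",
) -> RiskModel:
    """Fit the full risk model on a training set.

    Thresholds come from training controls only; directions (unless
    supplied) from training group means; weights from the training
    samples.  The returned model is frozen: apply it unchanged to
    validation samples with :func:`apply_risk_model`.
    """
    case_ids, control_ids = list(case_ids), list(control_ids)
    assays = list(assays) if assays is not None else expr.assay_ids
    if directions is None:
        directions = determine_directions(expr, case_ids, control_ids, assays)
    thresholds, weights, flags = {}, {}, {}
    labels = np.array([1] * len(case_ids) + [0] * len(control_ids))
    for a in assays:
        tau = reference_threshold(expr.expression.loc[control_ids, a], directions[a])
        thresholds[a] = tau
        col = expr.expression.loc[case_ids + control_ids, a].to_numpy()
        s = binarize_array(col, tau, directions[a], down_rule)
        fit = fit_weight(s, labels)
        weights[a] = fit.weight
        fl = []
        if fit.separation:
            fl.append("SEPARATION")
        if fit.degenerate:
            fl.append("DEGENERATE")
        flags[a] = fl
    return RiskModel(
        assays=assays,
        directions={a: directions[a] for a in assays},
        thresholds=thresholds,
        weights=weights,
        flags=flags,
        down_rule=down_rule,
    )


def apply_risk_model(model: RiskModel, expr: ExpressionMatrix, sample_ids=None) -> RiskScoreResult:
    """Score samples with a frozen model (no re-fitting)."""
    ids = list(sample_ids) if sample_ids is not None else expr.sample_ids
    s = pd.DataFrame(index=ids, columns=model.assays, dtype=float)
    for a in model.assays:
        col = expr.expression.loc[ids, a].to_numpy()
        s[a] = binarize_array(col, model.thresholds[a], model.directions[a], model.down_rule)
    w = np.array([model.weights[a] for a in model.assays])
    rsf = pd.Series(s.to_numpy() @ w, index=ids, name="rsf")
    return RiskScoreResult(s=s, rsf=rsf)
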