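"""Reference-interval thresholds, binarization, logistic weights, RSF."""

import json

import numpy as np
import pandas as pd
import pytest

from sermir import risk_score as rs
from sermir.datamodel import Direction, ExpressionMatrix


def expr_from_frame(frame: pd.DataFrame) -> ExpressionMatrix:
    return ExpressionMatrix(expression=frame, delta_ct=-np.log2(frame))


def test_reference_threshold_interpolated_percentiles():
    controls = np.arange(1, 101, dtype=float)
    # position 1 + (n-1)p: 95.05 for the upper, 5.95 for the lower bound
    assert rs.reference_threshold(controls, Direction.UP) == pytest.approx(95.05)
    assert rs.reference_threshold(controls, Direction.DOWN) == pytest.approx(5.95)
    assert rs.reference_threshold(np.full(25, 2.0), Direction.UP) == 2.0
    assert rs.reference_threshold(np.full(25, 2.0), Direction.DOWN) == 2.0
    with pytest.raises(ValueError, match="empty"):
        rs.reference_threshold([], Direction.UP)


def test_binarize_strict_inequalities_and_missing():
    assert rs.binarize(1.0, 1.0, Direction.UP) == 0  # tie scores 0
    assert rs.binarize(1.01, 1.0, Direction.UP) == 1
    assert rs.binarize(0.5, 1.0, Direction.UP) == 0
    assert rs.binarize(0.5, 1.0, Direction.DOWN) == 1  # below the 5th percentile
    assert rs.binarize(1.0, 1.0, Direction.DOWN) == 0
    assert rs.binarize(np.nan, 1.0, Direction.UP) == 0  # MISSING scores 0
    # the literal "above the lower bound" alternative is selectable
    assert rs.binarize(2.0, 1.0, Direction.DOWN, down_rule="above_lower") == 1


def test_fit_weight_equals_log_odds_ratio():
    s = np.array([1] * 15 + [0] * 5 + [1] * 2 + [0] * 18)
    y = np.array([1] * 20 + [0] * 20)
    fit = rs.fit_weight(s, y)
    assert not fit.separation and not fit.degenerate
    assert fit.weight == pytest.approx(np.log(27.0), abs=1e-6)


def test_fit_weight_balanced_table_is_zero():
    s = np.array([1] * 10 + [0] * 10 + [1] * 10 + [0] * 10)
    y = np.array([1] * 20 + [0] * 20)
    assert rs.fit_weight(s, y).weight == pytest.approx(0.0, abs=1e-8)


def test_fit_weight_separation_uses_haldane_anscombe():
    n1, n0 = 12, 9
    s = np.array([1] * n1 + [0] * n0)
    y = np.array([1] * n1 + [0] * n0)
    fit = rs.fit_weight(s, y)
    assert fit.separation
    expected = np.log((n1 + 0.5) * (n0 + 0.5) / (0.5 * 0.5))
    assert fit.weight == pytest.approx(expected, rel=1e-12)


def test_fit_weight_degenerate_and_errors():
    y = np.array([1, 1, 0, 0])
    assert rs.fit_weight(np.zeros(4), y).degenerate
    assert rs.fit_weight(np.zeros(4), y).weight == 0.0
    with pytest.raises(ValueError, match="both classes"):
        rs.fit_weight(np.array([0, 1]), np.array([1, 1]))
    with pytest.raises(ValueError, match="binary"):
        rs.fit_weight(np.array([0.5, 1]), np.array([0, 1]))


def test_fit_weight_iterative_matches_closed_form_log_or(rng):
    """The Newton fit of the univariate logistic slope equals ln(OR)
    whenever the 2x2 table has no zero cell."""
    for _ in range(100):
        n = int(rng.integers(20, 200))
        s = rng.integers(0, 2, n)
        y = rng.integers(0, 2, n)
        t = np.array(
            [[(s & y).sum(), ((1 - s) & y).sum()], [(s & (1 - y)).sum(), ((1 - s) & (1 - y)).sum()]]
        )
        if t.min() == 0:
            continue
        fit = rs.fit_weight(s, y)
        closed = np.log(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0]))
        assert fit.weight == pytest.approx(closed, abs=1e-6)


def test_risk_score_weighted_sum():
    assert rs.risk_score([0, 0, 0], [3.0, -1.0, 2.0]) == 0.0
    assert rs.risk_score([1, 0, 1], [1.0, 2.0, 3.0]) == 4.0
    perm = [2, 0, 1]
    s, w = np.array([1, 0, 1]), np.array([1.0, 2.0, 3.0])
    assert rs.risk_score(s[perm], w[perm]) == rs.risk_score(s, w)
    with pytest.raises(ValueError, match="length"):
        rs.risk_score([1, 0], [1.0])


def test_build_risk_model_controls_exceed_threshold_at_5_percent(rng):
    """Applying a frozen model to its own training controls flags ~5% of
    them per UP miRNA, by construction of the 95th percentile."""
    n_ctrl, n_case = 200, 50
    rates = []
    for _ in range(20):
        ctrl = rng.lognormal(0, 0.5, n_ctrl)
        case = rng.lognormal(0.8, 0.5, n_case)
        frame = pd.DataFrame(
            {"m": np.concatenate([case, ctrl])},
            index=[f"c{i}" for i in range(n_case)] + [f"h{i}" for i in range(n_ctrl)],
        )
        expr = expr_from_frame(frame)
        case_ids, ctrl_ids = list(frame.index[:n_case]), list(frame.index[n_case:])
        model = rs.build_risk_model(expr, case_ids, ctrl_ids)
        assert model.directions["m"] is Direction.UP
        scored = rs.apply_risk_model(model, expr, ctrl_ids)
        rates.append(scored.s["m"].mean())
    assert np.mean(rates) == pytest.approx(0.05, abs=0.01)


def test_single_mirna_model_rsf_ranks_like_s(rng):
    vals = np.concatenate([rng.lognormal(1.0, 0.5, 30), rng.lognormal(0, 0.5, 30)])
    frame = pd.DataFrame({"m": vals}, index=[f"s{i}" for i in range(60)])
    expr = expr_from_frame(frame)
    case_ids, ctrl_ids = list(frame.index[:30]), list(frame.index[30:])
    model = rs.build_risk_model(expr, case_ids, ctrl_ids)
    scored = rs.apply_risk_model(model, expr)
    w = model.weights["m"]
    # RSF is exactly w*s, so (for w > 0) ranking by RSF is ranking by s
    assert np.array_equal(scored.rsf.to_numpy(), w * scored.s["m"].to_numpy())
    assert w > 0


def test_model_json_roundtrip(tmp_path, rng):
    frame = pd.DataFrame(
        {"m1": rng.lognormal(0, 0.4, 80), "m2": rng.lognormal(0.3, 0.4, 80)},
        index=[f"s{i}" for i in range(80)],
    )
    expr = expr_from_frame(frame)
    model = rs.build_risk_model(expr, list(frame.index[:40]), list(frame.index[40:]))
    path = tmp_path / "model.json"
    model.to_json(path)
    back = rs.RiskModel.from_json(path)
    assert back.to_json() == model.to_json()
    assert json.loads(model.to_json())["down_rule"] == "below_lower"


def test_weights_nonnegative_when_directions_correct(rng):
    """With correctly specified directions and real signal, fitted
    weights are almost always nonnegative (RSF nondecreasing in s)."""
    n_ok = 0
    n_seeds = 50
    for _ in range(n_seeds):
        ctrl = rng.lognormal(0, 0.5, 60)
        case_up = rng.lognormal(1.0, 0.5, 60)
        case_dn = rng.lognormal(-1.0, 0.5, 60)
        frame = pd.DataFrame(
            {"up": np.concatenate([case_up, ctrl]), "dn": np.concatenate([case_dn, ctrl])},
            index=[f"x{i}" for i in range(120)],
        )
        expr = expr_from_frame(frame)
        model = rs.build_risk_model(expr, list(frame.index[:60]), list(frame.index[60:]))
        if all(w >= 0 for w in model.weights.values()):
            n_ok += 1
    assert n_ok / n_seeds >= 0.95
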