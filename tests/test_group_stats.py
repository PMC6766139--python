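"""Low-expression exclusion, descriptive summaries and two-group tests."""

import numpy as np
import pytest
from scipy import stats as sps

from sermir import group_stats as gs
from sermir.datamodel import Group, Phase, SampleRecord
from sermir.normalization import normalize_matrix
from tests.conftest import make_ct_matrix


def censoring_matrix(n_high, n_total):
    vals = {}
    for i in range(n_total):
        ct = 37.0 if i < n_high else 30.0
        vals[f"s{i}"] = {"m": ct, "ok": 25.0}
    return make_ct_matrix(vals)


def test_low_expression_filter_majority_rule():
    excl = gs.low_expression_filter(censoring_matrix(60, 100))
    assert "m" in excl.excluded and excl.excluded["m"] == pytest.approx(0.6)
    assert "ok" in excl.retained
    # exactly half above the cutoff is retained (strict majority rule)
    excl = gs.low_expression_filter(censoring_matrix(50, 100))
    assert "m" in excl.retained
    excl = gs.low_expression_filter(censoring_matrix(0, 10))
    assert excl.excluded == {}


def test_low_expression_filter_counts_censored_entries():
    vals = {f"s{i}": {"m": None if i < 6 else 30.0} for i in range(10)}
    excl = gs.low_expression_filter(make_ct_matrix(vals))
    assert "m" in excl.excluded


def test_low_expression_filter_rejects_bad_fraction():
    with pytest.raises(ValueError):
        gs.low_expression_filter(censoring_matrix(0, 10), max_fraction=1.0)


def test_students_t_identity_and_known_value():
    res = gs.students_t([1, 2, 3], [1, 2, 3])
    assert res.statistic == 0.0 and res.p_value == 1.0
    res = gs.students_t([1, 2, 3], [4, 5, 6])
    # pooled sd = 1, se = sqrt(2/3), t = -3/se
    expected_t = -3.0 / np.sqrt(2.0 / 3.0)
    assert res.statistic == pytest.approx(expected_t, abs=1e-4)
    assert res.statistic == pytest.approx(-3.674, abs=1e-3)
    assert res.df == 4
    assert res.p_value == pytest.approx(2 * sps.t.sf(abs(expected_t), 4), rel=1e-12)


def test_students_t_antisymmetry():
    a, b = [1.0, 2.0, 5.0, 7.0], [2.0, 2.5, 3.0]
    r1, r2 = gs.students_t(a, b), gs.students_t(b, a)
    assert r1.statistic == pytest.approx(-r2.statistic, rel=1e-12)
    assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)


def test_students_t_degenerate_variance():
    with pytest.raises(ValueError, match="degenerate"):
        gs.students_t([1, 1, 1], [2, 2, 2])
    with pytest.raises(ValueError, match="two finite"):
        gs.students_t([1.0], [1, 2, 3])


def test_t_from_summary_known_value_and_consistency(rng):
    res = gs.t_from_summary(0, 1, 10, 1, 1, 10)
    assert res.statistic == pytest.approx(-2.2361, abs=1e-4)
    assert res.df == 18
    assert gs.t_from_summary(5, 2, 8, 5, 2, 8).p_value == 1.0
    # matches the raw-data test when summaries come from the same data
    a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1.3, 15)
    raw = gs.students_t(a, b)
    summ = gs.t_from_summary(
        a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
    )
    assert summ.statistic == pytest.approx(raw.statistic, abs=1e-9)
    assert summ.p_value == pytest.approx(raw.p_value, abs=1e-9)


def pearson_chi2(t):
    """Independent oracle: N(ad-bc)^2 / (r1 r2 c1 c2)."""
    (a, b), (c, d) = t
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


def test_chi_square_examples_and_symmetry():
    res = gs.chi_square_2x2([[10, 10], [10, 10]])
    assert res.statistic == 0.0 and res.p_value == 1.0
    res = gs.chi_square_2x2([[20, 10], [10, 20]])
    assert res.statistic == pytest.approx(20.0 / 3.0, rel=1e-12)
    assert res.df == 1
    t = [[7, 3], [2, 11]]
    assert gs.chi_square_2x2(t).statistic == pytest.approx(
        gs.chi_square_2x2(np.transpose(t)).statistic, rel=1e-12
    )
    with pytest.raises(ValueError, match="margin"):
        gs.chi_square_2x2([[0, 0], [5, 5]])


def test_chi_square_matches_pearson_formula_on_random_tables(rng):
    for _ in range(200):
        t = rng.integers(1, 16, size=(2, 2))
        assert gs.chi_square_2x2(t).statistic == pytest.approx(
            pearson_chi2(t), rel=1e-10
        )


def test_chi_square_continuity_correction_flag():
    plain = gs.chi_square_2x2([[20, 10], [10, 20]]).statistic
    corrected = gs.chi_square_2x2([[20, 10], [10, 20]], correction=True).statistic
    assert corrected < plain


def test_summarize_groups_sem_and_missing():
    matrix = make_ct_matrix(
        {
            "a1": {"let-7d": 25.0, "let-7g": 25.0, "let-7i": 25.0, "m": 25.0},
            "a2": {"let-7d": 25.0, "let-7g": 25.0, "let-7i": 25.0, "m": 24.0},
            "a3": {"let-7d": 25.0, "let-7g": 25.0, "let-7i": 25.0, "m": 25.0 - np.log2(3)},
            "b1": {"let-7d": 25.0, "let-7g": 25.0, "let-7i": 25.0, "m": 25.0},
            "b2": {"let-7d": 25.0, "let-7g": 25.0, "let-7i": 25.0, "m": 25.0},
            "b3": {"let-7d": 25.0, "let-7g": 25.0, "let-7i": 25.0, "m": None},
        }
    )
    records = [
        SampleRecord(s, Group.PTC if s.startswith("a") else Group.CONTROL, Phase.TRAINING)
        for s in matrix.sample_ids
    ]
    expr = normalize_matrix(matrix)
    table = gs.summarize_groups(expr, records).set_index("group")
    ptc = table.loc["PTC"]  # expressions 1, 2, 3
    assert ptc["n"] == 3
    assert ptc["mean"] == pytest.approx(2.0)
    assert ptc["sd"] == pytest.approx(1.0)
    assert ptc["sem"] == pytest.approx(1.0 / np.sqrt(3), abs=1e-4)
    ctrl = table.loc["CONTROL"]  # constant group, one MISSING excluded
    assert ctrl["n"] == 2 and ctrl["sem"] == 0.0


def test_type_one_error_calibrated_under_lognormal_null(rng):
    """Fraction of p < 0.05 under a same-distribution null is ~5%."""
    n_reps, n = 2000, 50
    hits = 0
    for _ in range(n_reps):
        a = np.exp(rng.normal(0, 0.5, n))
        b = np.exp(rng.normal(0, 0.5, n))
        if gs.students_t(a, b).p_value < 0.05:
            hits += 1
    assert abs(hits / n_reps - 0.05) <= 0.015


def test_benjamini_hochberg_is_monotone():
    p = [0.001, 0.01, 0.02, 0.5, 0.9]
    q = gs.benjamini_hochberg(p)
    assert (np.diff(q) >= 0).all() and (q >= p).all()
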