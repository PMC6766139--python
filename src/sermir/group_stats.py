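"""Group descriptive statistics and two-group tests.

The study protocol compares per-miRNA relative expression between
clinical groups with a pooled-variance (Student's) two-sample t test and
compares categorical demographics with a two-sided Pearson chi-square
test.  Assays undetectable in most samples are excluded up front
(Cq above 35 in more than half the samples, by default).  No
multiple-testing correction is applied by default, matching the original
analysis; Benjamini-Hochberg is available as a clearly optional extra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CtMatrix, ExpressionMatrix, Group, SampleRecord

DEFAULT_CQ_CUTOFF = 35.0
DEFAULT_MAX_FRACTION = 0.5


@dataclass
class TestResult:
    comparison: str
    statistic: float
    df: float
    p_value: float


@dataclass
class ExclusionLog:
    retained: list[str]
    excluded: dict[str, float] = field(default_factory=dict)  # assay -> offending fraction


def low_expression_filter(
    matrix: CtMatrix,
    cq_cutoff: float = DEFAULT_CQ_CUTOFF,
    max_fraction: float = DEFAULT_MAX_FRACTION,
    assays: list[str] | None = None,
) -> ExclusionLog:
    """Exclude assays whose Cq exceeds ``cq_cutoff`` (or is censored) in
    strictly more than ``max_fraction`` of samples.

    "Most samples" is operationalized as a strict majority by default.
    Entries never measured for a sample do not count against the assay.
    """
    if not (0 < max_fraction < 1):
        raise ValueError("max_fraction must be in (0, 1)")
    assays = list(assays) if assays is not None else matrix.assay_ids
    retained, excluded = [], {}
    for assay in assays:
        measured = matrix.n_replicates[assay] > 0
        n = int(measured.sum())
        if n == 0:
            retained.append(assay)
            continue
        ct = matrix.ct.loc[measured, assay]
        high = (~np.isfinite(ct)) | (ct > cq_cutoff)
        frac = float(high.sum()) / n
        if frac > max_fraction:
            excluded[assay] = frac
        else:
            retained.append(assay)
    return ExclusionLog(retained=retained, excluded=excluded)


def students_t(values_a, values_b, comparison: str = "", welch: bool = False) -> TestResult:
    """Two-sample t test, pooled variance by default (Welch behind a flag).

    Degenerate inputs: zero pooled variance with equal means gives
    t = 0, p = 1; zero pooled variance with unequal means is an error.
    """
    a = np.asarray([v for v in np.ravel(values_a) if np.isfinite(v)], dtype=float)
    b = np.asarray([v for v in np.ravel(values_b) if np.isfinite(v)], dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two finite values")
    df = a.size + b.size - 2
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TestResult(comparison, 0.0, float(df), 1.0)
        raise ValueError("zero pooled variance with unequal means: degenerate t test")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    if welch:
        df = res.df
    return TestResult(comparison, float(res.statistic), float(df), float(res.pvalue))


def t_from_summary(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
    comparison: str = "",
) -> TestResult:
    """Pooled t test from group summaries (mean, SD, n), as used for
    demographics reported only as mean +/- SD."""
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be nonnegative")
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    df = n_a + n_b - 2
    if sd_a == 0 and sd_b == 0:
        if mean_a == mean_b:
            return TestResult(comparison, 0.0, float(df), 1.0)
        raise ValueError("zero pooled variance with unequal means: degenerate t test")
    t, p = stats.ttest_ind_from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=True)
    return TestResult(comparison, float(t), float(df), float(p))


def chi_square_2x2(counts, comparison: str = "", correction: bool = False) -> TestResult:
    """Pearson chi-square on a 2x2 table, two-sided, df = 1.

    Continuity correction off by default; any zero margin is an error.
    """
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("counts must be a 2x2 nonnegative table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin in 2x2 table")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=correction)
    return TestResult(comparison, float(chi2), float(df), float(p))


def summarize_groups(
    expr: ExpressionMatrix,
    records: list[SampleRecord],
    groups: list[Group] | None = None,
) -> pd.DataFrame:
    """Per miRNA x group n, mean, SD and SEM of relative expression over
    non-MISSING entries.  SEM = SD/sqrt(n); groups with n < 2 report NaN
    SD/SEM."""
    by_id = {r.sample_id: r for r in records}
    labels = pd.Series(
        {s: by_id[s].group.value for s in expr.sample_ids if s in by_id}, name="group"
    )
    if groups is not None:
        wanted = {g.value for g in groups}
        labels = labels[labels.isin(wanted)]
    rows = []
    for assay in expr.assay_ids:
        col = expr.expression.loc[labels.index, assay]
        for g, vals in col.groupby(labels):
            v = vals.dropna().to_numpy()
            n = v.size
            mean = float(v.mean()) if n else np.nan
            sd = float(v.std(ddof=1)) if n >= 2 else np.nan
            rows.append(
                {
                    "assay_id": assay,
                    "group": g,
                    "n": n,
                    "mean": mean,
                    "sd": sd,
                    "sem": sd / np.sqrt(n) if n >= 2 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Optional BH-adjusted p values (an extension beyond the original
    analysis, which corrected nothing)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]
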