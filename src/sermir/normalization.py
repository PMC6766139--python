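"""Composite-reference delta-Ct normalization.

Serum has no agreed single housekeeping miRNA; this pipeline normalizes
each sample against the composite of let-7d, let-7g and let-7i, a trio
shown to be stable across healthy and diseased sera.  The composite
reference CT is the arithmetic mean of the available reference CTs
(equivalently, the geometric mean of their linear abundances), and

    dCT      = CT_target - CT_reference
    level    = 2^-dCT                      (relative expression)
    ddCT     = dCT_case - dCT_comparator
    fold chg = 2^-ddCT                     (>1 = up in case)

assuming perfect doubling per cycle (efficiency 2, no correction).
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .datamodel import (
    DEFAULT_REFERENCE_ASSAYS,
    CtMatrix,
    ExpressionMatrix,
)

log = logging.getLogger(__name__)


def composite_reference_ct(reference_cts: Iterable[float]) -> float:
    """Arithmetic mean of the available (finite) reference CTs.

    Raises ValueError when no finite reference CT is available, i.e. the
    sample cannot be normalized.
    """
    vals = np.asarray([c for c in reference_cts if np.isfinite(c)], dtype=float)
    if vals.size == 0:
        raise ValueError("no finite reference CT: sample cannot be normalized")
    return float(vals.mean())


def delta_ct(target_ct: float, reference_ct: float) -> float:
    """dCT = CT_target - CT_reference (both finite)."""
    if not (np.isfinite(target_ct) and np.isfinite(reference_ct)):
        raise ValueError("delta_ct requires finite target and reference CT")
    return float(target_ct) - float(reference_ct)


def relative_expression(dct):
    """Relative level 2^-dCT (scalar or array)."""
    out = np.exp2(-np.asarray(dct, dtype=float))
    return float(out) if out.ndim == 0 else out


def fold_change_pools(dct_case: float, dct_comparator: float) -> float:
    """Pooled-screening fold change 2^-ddCT with ddCT = dCT_case - dCT_comparator."""
    return float(2.0 ** -(float(dct_case) - float(dct_comparator)))


def normalize_matrix(
    matrix: CtMatrix,
    reference_assays=DEFAULT_REFERENCE_ASSAYS,
) -> ExpressionMatrix:
    """Normalize a CtMatrix to its composite reference per sample.

    Samples with one or two censored references are normalized on the
    remaining references and flagged as degraded; samples with all
    references censored/absent are dropped.  A censored target CT yields
    a MISSING (NaN) expression entry, never an imputed value.
    """
    refs = [a for a in reference_assays if a in matrix.assay_ids]
    if not refs:
        raise ValueError(
            f"none of the reference assays {tuple(reference_assays)} present in the CT table"
        )
    targets = [a for a in matrix.assay_ids if a not in set(reference_assays)]
    ref_ct = matrix.ct[refs]
    n_ref = ref_ct.notna().sum(axis=1)
    usable = n_ref > 0
    dropped = [s for s in matrix.sample_ids if not usable[s]]
    degraded = [s for s in matrix.sample_ids if usable[s] and n_ref[s] < len(reference_assays)]
    if dropped:
        log.warning("dropping %d sample(s) with no usable reference assay: %s", len(dropped), dropped)
    if degraded:
        log.info("%d sample(s) normalized on a degraded reference set", len(degraded))

    keep = [s for s in matrix.sample_ids if usable[s]]
    composite = ref_ct.loc[keep].mean(axis=1, skipna=True)
    dct = matrix.ct.loc[keep, targets].sub(composite, axis=0)
    expr = np.exp2(-dct)
    return ExpressionMatrix(
        expression=expr,
        delta_ct=dct,
        degraded_reference=degraded,
        dropped_samples=dropped,
    )


def pool_delta_ct(
    pool_ct: pd.Series,
    reference_assays=DEFAULT_REFERENCE_ASSAYS,
    internal_control: str = "reference_mean",
) -> pd.Series:
    """Normalize one pool's raw CT profile to an internal control.

    ``internal_control`` is either ``"reference_mean"`` (mean CT of the
    designated reference assays within the pool, the default) or
    ``"global_mean"`` (mean CT of every detected assay on the card).
    """
    if internal_control == "reference_mean":
        refs = [a for a in reference_assays if a in pool_ct.index and np.isfinite(pool_ct[a])]
        if not refs:
            raise ValueError("pool lacks all reference assays")
        ctrl = float(pool_ct[refs].mean())
    elif internal_control == "global_mean":
        ctrl = float(pool_ct[np.isfinite(pool_ct)].mean())
    else:
        raise ValueError(f"unknown internal control {internal_control!r}")
    return pool_ct - ctrl
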