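"""Pooled-array candidate screening.

The discovery stage profiles hundreds of miRNAs on pooled sera (one pool
per group) and keeps an assay as a biomarker candidate when it satisfies
all of:

1. raw CT in the case pool strictly below ``ct_cutoff`` (abundant enough
   to quantify reliably in individual sera);
2. at least ``fc_cutoff``-fold change — in either direction — between
   the case pool and *any* comparator pool;
3. membership in a user-supplied literature whitelist (curation cannot
   be automated; an empty whitelist disables the criterion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import PoolProfile
from .normalization import fold_change_pools

DEFAULT_CT_CUTOFF = 28.0
DEFAULT_FC_CUTOFF = 5.0


@dataclass
class CandidateReport:
    """Per-assay screening decisions with the full criterion trail."""

    table: pd.DataFrame  # index = assay, columns: case_ct, fc_<group>..., ct_pass, fc_pass, whitelist_pass, indeterminate, candidate

    @property
    def candidates(self) -> list[str]:
        return list(self.table.index[self.table["candidate"]])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="assay_id")


def screen_candidates(
    case: PoolProfile,
    comparators: list[PoolProfile],
    ct_cutoff: float = DEFAULT_CT_CUTOFF,
    fc_cutoff: float = DEFAULT_FC_CUTOFF,
    whitelist: set[str] | None = None,
) -> CandidateReport:
    """Apply the three candidate criteria to one case pool.

    Fold change is computed on normalized pool dCT (2^-ddCT) against each
    comparator; the criterion passes if ``max(FC, 1/FC) >= fc_cutoff``
    for at least one comparator.  The CT criterion uses the *raw* case
    pool CT and is strict (< cutoff).  An assay quantified in the case
    pool but in no comparator is flagged indeterminate and is never a
    candidate.
    """
    if ct_cutoff <= 0:
        raise ValueError("ct_cutoff must be positive")
    if fc_cutoff < 1:
        raise ValueError("fc_cutoff must be >= 1")
    if case.raw_ct is None:
        raise ValueError("case pool must carry raw CT values for the CT criterion")
    whitelist = set(whitelist or ())

    rows = {}
    for assay in case.delta_ct.index:
        raw = case.raw_ct.get(assay, np.nan)
        dct = case.delta_ct[assay]
        row: dict[str, object] = {"case_ct": raw}
        fcs = []
        for comp in comparators:
            fc = np.nan
            if (
                assay in comp.delta_ct.index
                and np.isfinite(comp.delta_ct[assay])
                and np.isfinite(dct)
            ):
                fc = fold_change_pools(dct, comp.delta_ct[assay])
                fcs.append(fc)
            row[f"fc_vs_{comp.group.value}"] = fc
        ct_pass = bool(np.isfinite(raw) and raw < ct_cutoff)
        indeterminate = len(fcs) == 0
        fc_pass = bool(any(max(fc, 1.0 / fc) >= fc_cutoff for fc in fcs))
        wl_pass = (not whitelist) or (assay in whitelist)
        row.update(
            ct_pass=ct_pass,
            fc_pass=fc_pass,
            whitelist_pass=wl_pass,
            indeterminate=indeterminate,
            candidate=ct_pass and fc_pass and wl_pass and not indeterminate,
        )
        rows[assay] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    return CandidateReport(table)


def read_whitelist(path) -> set[str]:
    """One assay id per line; blank lines and '#' comments ignored."""
    out = set()
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s and not s.startswith("#"):
                out.add(s)
    return out
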