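"""Readers/writers for long-format CT tables and study-design validation.

The canonical on-disk format is a long CSV with header
``sample_id,group,phase,assay_id,replicate,ct`` — one row per technical
replicate.  Non-numeric CT cells (empty, "Undetermined", "NA") and CT
values above ``max_cycles`` are treated as censored (assay not detected
within the run).  Replicates are collapsed by arithmetic mean of CT
before any downstream step.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    DEFAULT_MAX_CYCLES,
    DEFAULT_REFERENCE_ASSAYS,
    CtMatrix,
    Group,
    Phase,
    SampleRecord,
    StudyDesign,
)

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("sample_id", "group", "assay_id", "ct")
CENSORED_SENTINELS = {"", "undetermined", "undet", "na", "nan", "censored", "nd"}


def _parse_ct(value) -> float:
    """Return a finite CT or NaN for censored sentinels. Raises on junk
    that is neither numeric nor a known sentinel."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    s = str(value).strip()
    if s.lower() in CENSORED_SENTINELS:
        return np.nan
    try:
        return float(s)
    except ValueError as exc:
        raise ValueError(f"unparseable CT value {value!r}") from exc


def read_ct_table(
    path,
    schema: dict[str, str] | None = None,
    max_cycles: float = DEFAULT_MAX_CYCLES,
) -> tuple[CtMatrix, list[SampleRecord]]:
    """Read a long-format CT CSV into a CtMatrix plus sample records.

    Parameters
    ----------
    path
        CSV file with at least sample_id, group, assay_id and ct columns
        (``phase`` and ``replicate`` are optional; ``replicate`` defaults
        to 1, ``phase`` to TRAINING).
    schema
        Optional mapping from required column name to the actual column
        name in the file.
    max_cycles
        CTs above this are coerced to censored with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"CT table {path} missing required columns: {missing}")
    if "replicate" not in df.columns:
        df["replicate"] = "1"
    if "phase" not in df.columns:
        df["phase"] = Phase.TRAINING.value

    dup = df.duplicated(subset=["sample_id", "assay_id", "replicate"], keep=False)
    if dup.any():
        first = df[dup].iloc[0]
        raise ValueError(
            "duplicate (sample, assay, replicate) rows, e.g. row "
            f"{df.index[dup][0] + 2} of {path.name}: "
            f"({first['sample_id']}, {first['assay_id']}, rep {first['replicate']})"
        )

    records: dict[str, SampleRecord] = {}
    for i, row in df.iterrows():
        sid = row["sample_id"]
        try:
            group = Group(row["group"])
        except ValueError:
            raise ValueError(
                f"unknown group label {row['group']!r} in row {i + 2} "
                f"(sample {sid!r}) of {path.name}"
            ) from None
        phase = Phase(row["phase"])
        if sid not in records:
            records[sid] = SampleRecord(
                sample_id=sid,
                group=group,
                phase=phase,
                age=float(row["age"]) if row.get("age") not in (None, "") else None,
                sex=row.get("sex") or None,
            )
        elif records[sid].group is not group:
            raise ValueError(f"sample {sid!r} assigned to two groups")

    ct_vals = df["ct"].map(_parse_ct)
    over = ct_vals > max_cycles
    if over.any():
        log.warning(
            "%d CT values above max_cycles=%.0f coerced to censored",
            int(over.sum()), max_cycles,
        )
        ct_vals = ct_vals.mask(over)
    work = df.assign(_ct=ct_vals)

    sample_order = list(dict.fromkeys(df["sample_id"]))
    assay_order = list(dict.fromkeys(df["assay_id"]))
    grouped = work.groupby(["sample_id", "assay_id"], sort=False)["_ct"]
    mean_ct = grouped.mean().unstack().reindex(index=sample_order, columns=assay_order)
    n_rep = (
        grouped.size().unstack().reindex(index=sample_order, columns=assay_order)
        .fillna(0).astype(int)
    )
    n_finite = (
        grouped.count().unstack().reindex(index=sample_order, columns=assay_order)
        .fillna(0).astype(int)
    )
    # measured but never yielding a finite CT -> censored
    censored = (n_rep > 0) & (n_finite == 0)
    matrix = CtMatrix(mean_ct, censored, n_rep, max_cycles=max_cycles)
    return matrix, list(records.values())


def write_ct_table(path, matrix: CtMatrix, records: list[SampleRecord]) -> None:
    """Write a CtMatrix back to the long CSV format (collapsed replicates:
    one row per measured sample/assay entry, censored entries written as
    ``Undetermined``)."""
    by_id = {r.sample_id: r for r in records}
    rows = []
    ct = matrix.ct
    for sid in matrix.sample_ids:
        rec = by_id[sid]
        for aid in matrix.assay_ids:
            nrep = int(matrix.n_replicates.at[sid, aid])
            if nrep == 0:
                continue
            v = ct.at[sid, aid]
            rows.append(
                {
                    "sample_id": sid,
                    "group": rec.group.value,
                    "phase": rec.phase.value,
                    "assay_id": aid,
                    "replicate": 1,
                    "ct": "Undetermined" if not np.isfinite(v) else repr(float(v)),
                }
            )
    pd.DataFrame(rows, columns=["sample_id", "group", "phase", "assay_id", "replicate", "ct"]).to_csv(
        path, index=False
    )


@dataclass
class ValidationReport:
    """Report-only design validation; ``fatal`` blocks the pipeline."""

    warnings: list[str] = field(default_factory=list)
    fatal: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.fatal

    @property
    def empty(self) -> bool:
        return not self.warnings and not self.fatal


def validate_design(
    matrix: CtMatrix,
    records: list[SampleRecord],
    design: StudyDesign | None = None,
    reference_assays=DEFAULT_REFERENCE_ASSAYS,
) -> ValidationReport:
    """Check reference coverage per sample and group sizes against a design.

    A sample with some (but not all) reference assays detected is a
    warning; a sample with no usable reference assay is fatal — it cannot
    be normalized at all.
    """
    report = ValidationReport()
    refs = [a for a in reference_assays if a in matrix.assay_ids]
    for a in reference_assays:
        if a not in matrix.assay_ids:
            report.fatal.append(f"reference assay {a!r} absent from the CT table")
    if not refs:
        return report
    finite = matrix.ct[refs].notna()
    for sid in matrix.sample_ids:
        n_ok = int(finite.loc[sid].sum())
        if n_ok == 0:
            report.fatal.append(f"sample {sid!r} lacks all reference assays")
        elif n_ok < len(reference_assays):
            lacking = [a for a in reference_assays if a not in refs or not finite.at[sid, a]]
            report.warnings.append(
                f"sample {sid!r} missing reference assay(s) {lacking}; "
                "normalized on the remaining references"
            )
    if design is not None:
        counts: dict[tuple[Phase, Group], int] = {}
        for r in records:
            key = (r.phase, r.group)
            counts[key] = counts.get(key, 0) + 1
        for key, expected in design.group_sizes.items():
            got = counts.get(key, 0)
            if got != expected:
                report.warnings.append(
                    f"{key[0].value}/{key[1].value}: expected {expected} samples, found {got}"
                )
        groups = {r.group for r in records}
        for a, b in design.comparisons:
            if a not in groups or b not in groups:
                report.warnings.append(f"comparison {a.value} vs {b.value} has an empty arm")
    return report


def write_manifest(path, *, seed: int | None, config: dict) -> None:
    """JSON run manifest: config echo, seed, package version. Content is a
    pure function of its inputs so reruns are byte-identical."""
    from . import __version__

    payload = {"package": "sermir", "version": __version__, "seed": seed, "config": config}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
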