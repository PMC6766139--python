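"""Domain types for serum-miRNA qPCR studies.

A study is a set of serum samples (cases and controls, assigned to the
pooled-screening, training or validation phase) measured on a set of
TaqMan assays.  Raw measurements are threshold-cycle (CT/Cq) values;
an assay that never crosses threshold within the run's cycle limit is
*censored* (recorded as "Undetermined" by the instrument).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_REFERENCE_ASSAYS = ("let-7d", "let-7g", "let-7i")
DEFAULT_MAX_CYCLES = 40.0


class Group(str, enum.Enum):
    """Clinical group of a sample."""

    PTC = "PTC"
    BENIGN = "BENIGN"
    MTC = "MTC"
    CONTROL = "CONTROL"


class Phase(str, enum.Enum):
    """Study phase a sample belongs to."""

    SCREEN_POOL = "SCREEN_POOL"
    TRAINING = "TRAINING"
    VALIDATION = "VALIDATION"


class Role(str, enum.Enum):
    TARGET = "TARGET"
    REFERENCE = "REFERENCE"


class Direction(str, enum.Enum):
    """Case-vs-control regulation of a miRNA."""

    UP = "UP"
    DOWN = "DOWN"


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    group: Group
    phase: Phase
    age: float | None = None
    sex: str | None = None


@dataclass(frozen=True)
class AssayAnnotation:
    assay_id: str
    role: Role


def make_annotations(
    assay_ids, reference_assays=DEFAULT_REFERENCE_ASSAYS
) -> list[AssayAnnotation]:
    ref = set(reference_assays)
    return [
        AssayAnnotation(a, Role.REFERENCE if a in ref else Role.TARGET)
        for a in assay_ids
    ]


@dataclass
class CtMatrix:
    """Samples x assays matrix of replicate-averaged CT values.

    ``ct`` holds finite CT values with NaN wherever no finite CT exists;
    ``censored`` marks entries that were measured but undetected (either
    reported as a sentinel or above ``max_cycles``); ``n_replicates``
    counts collapsed technical replicates (0 = entry never measured).
    """

    ct: pd.DataFrame
    censored: pd.DataFrame
    n_replicates: pd.DataFrame
    max_cycles: float = DEFAULT_MAX_CYCLES

    def __post_init__(self) -> None:
        for other in (self.censored, self.n_replicates):
            if not (
                other.index.equals(self.ct.index)
                and other.columns.equals(self.ct.columns)
            ):
                raise ValueError("CtMatrix component frames must share labels")
        finite = self.ct.to_numpy()
        bad = np.isfinite(finite) & ((finite <= 0) | (finite > self.max_cycles))
        if bad.any():
            raise ValueError(
                "finite CT values must lie in (0, max_cycles]; "
                f"found {int(bad.sum())} offending entries"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ct.index)

    @property
    def assay_ids(self) -> list[str]:
        return list(self.ct.columns)

    def subset_samples(self, sample_ids) -> "CtMatrix":
        idx = list(sample_ids)
        return CtMatrix(
            self.ct.loc[idx],
            self.censored.loc[idx],
            self.n_replicates.loc[idx],
            self.max_cycles,
        )

    def n_finite(self) -> int:
        return int(np.isfinite(self.ct.to_numpy()).sum())


@dataclass
class StudyDesign:
    """Group sizes per phase, pool composition and comparison pairs."""

    group_sizes: dict[tuple[Phase, Group], int]
    pools: dict[Group, list[str]] = field(default_factory=dict)
    comparisons: list[tuple[Group, Group]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b in self.comparisons:
            if a == b:
                raise ValueError(f"comparison must name two distinct groups, got {a!r} twice")


@dataclass
class ExpressionMatrix:
    """Per-sample relative expression 2^-dCT after composite-reference
    normalization, with the companion dCT matrix.

    NaN marks MISSING entries (target CT censored, or no usable
    reference).  ``degraded_reference`` lists samples normalized on
    fewer than the full reference set.
    """

    expression: pd.DataFrame
    delta_ct: pd.DataFrame
    degraded_reference: list[str] = field(default_factory=list)
    dropped_samples: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expression.index)

    @property
    def assay_ids(self) -> list[str]:
        return list(self.expression.columns)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        idx = list(sample_ids)
        return ExpressionMatrix(
            self.expression.loc[idx],
            self.delta_ct.loc[idx],
            [s for s in self.degraded_reference if s in set(idx)],
            self.dropped_samples,
        )


@dataclass
class PoolProfile:
    """Per-assay normalized dCT of one pooled serum sample."""

    group: Group
    delta_ct: pd.Series  # index = assay ids
    raw_ct: pd.Series | None = None  # raw pool CT, for the CT-cutoff criterion
    members: list[str] = field(default_factory=list)
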