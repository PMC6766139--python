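"""Synthetic serum-miRNA qPCR studies.

The generator emits CT-level data with the statistical structure the
analysis assumes:

* a per-sample *input-amount shift* — the composite reference CT drawn
  as N(ref_ct_mean, ref_ct_sd), shared by every assay of that sample
  (serum RNA yield varies sample to sample);
* per-miRNA biological variation placed on dCT, i.e. lognormal relative
  expression, with the dCT mean offset so that the *arithmetic* mean of
  2^-dCT equals the configured group mean level exactly;
* per-measurement technical noise (cycles) on every CT;
* detection-limit censoring: CTs above the instrument cutoff are
  reported as undetected;
* the four-group case-control design with its training/validation
  split, plus pooled screening profiles built by averaging member
  *linear* abundances (mixing equal serum volumes mixes molecules, not
  CT values).

Default parameters reproduce the published study conditions: group
sizes 100/91/15/89, splits 36/36/32 and 64/55/57, six-miRNA panel group
means taken from the validation-set summary tables, biological CVs
derived from the control-group SEMs (CV = SEM * sqrt(n) / mean), two
low-abundance decoy assays exercising the Cq>35 exclusion, and a
756-assay screening universe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import (
    CtMatrix,
    Direction,
    Group,
    Phase,
    PoolProfile,
    SampleRecord,
)

LN2 = math.log(2.0)

# Validation-set group mean levels (relative to let-7d/g/i) and control
# SEMs for the six-miRNA panel; control n = 57.
PANEL_TABLE = {
    # assay: (ptc, benign, control, control_sem)
    "miR-222-3p": (0.415, 0.390, 0.290, 0.020),
    "miR-17-5p": (1.590, 1.771, 1.152, 0.086),
    "miR-451a": (0.964, 0.862, 0.639, 0.030),
    "miR-146a-5p": (1.627, 1.816, 2.065, 0.113),
    "miR-132-3p": (1.442, 1.566, 2.052, 0.104),
    "miR-183-3p": (0.527, 0.500, 0.733, 0.035),
}
# Matched-subset (n = 15 each) group means and control SEMs for the
# aggressive-carcinoma arm, three up-regulated miRNAs.
MTC_TABLE = {
    # assay: (mtc, benign, control, control_sem)
    "miR-222-3p": (0.731, 0.376, 0.253, 0.028),
    "miR-17-5p": (2.719, 1.669, 1.079, 0.163),
    "miR-451a": (0.803, 0.836, 0.629, 0.059),
}
MTC_N = 15
DECOY_ASSAYS = ("miR-151-3p", "miR-19b-3p")


@dataclass(frozen=True)
class AssaySpec:
    """One target miRNA: control-group mean relative level, biological
    CV (SD/mean on the linear scale), and per-group fold changes."""

    control_mean: float
    cv: float
    fold_changes: dict[str, float] = field(default_factory=dict)  # group name -> FC

    def fc(self, group: Group) -> float:
        if group is Group.CONTROL:
            return 1.0
        return float(self.fold_changes.get(group.value, 1.0))


@dataclass
class SimulationConfig:
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"PTC": 100, "BENIGN": 91, "MTC": 15, "CONTROL": 89}
    )
    training_sizes: dict[str, int] = field(
        default_factory=lambda: {"PTC": 36, "BENIGN": 36, "CONTROL": 32}
    )
    assays: dict[str, AssaySpec] = field(default_factory=dict)
    reference_assays: tuple[str, ...] = ("let-7d", "let-7g", "let-7i")
    ref_ct_mean: float = 25.0
    ref_ct_sd: float = 1.0
    tech_sd: float = 0.25
    censor_cutoff: float = 40.0
    pool_size: int = 20
    screen_universe: int = 756
    seed: int = 0

    def validate(self) -> None:
        for name, val in (
            ("ref_ct_sd", self.ref_ct_sd),
            ("tech_sd", self.tech_sd),
        ):
            if val < 0:
                raise ValueError(f"{name} must be >= 0, got {val}")
        if self.censor_cutoff <= 0:
            raise ValueError("censor_cutoff must be positive")
        if self.pool_size <= 0:
            raise ValueError("pool_size must be positive")
        for a, spec in self.assays.items():
            if spec.control_mean <= 0:
                raise ValueError(f"assays[{a!r}].control_mean must be > 0")
            if spec.cv < 0:
                raise ValueError(f"assays[{a!r}].cv must be >= 0")
            for g, fc in spec.fold_changes.items():
                if fc <= 0:
                    raise ValueError(f"assays[{a!r}].fold_changes[{g!r}] must be > 0")
        for g, n_train in self.training_sizes.items():
            if n_train > self.group_sizes.get(g, 0):
                raise ValueError(f"training size for {g} exceeds group size")


def _bio_sd_cycles(cv: float) -> float:
    """dCT standard deviation (cycles) giving a lognormal level with the
    requested linear-scale CV."""
    return math.sqrt(math.log1p(cv * cv)) / LN2


def _dct_mean(level_mean: float, sd_cycles: float) -> float:
    """dCT mean such that E[2^-dCT] equals ``level_mean`` for normal dCT
    with SD ``sd_cycles``."""
    return -math.log2(level_mean) + LN2 * sd_cycles**2 / 2.0


@dataclass
class GroundTruth:
    """Planted per-assay, per-group truth emitted with every dataset."""

    table: pd.DataFrame  # columns: assay_id, group, mean_dct, mean_level, fold_change, direction

    def direction(self, assay: str, group: str = "PTC") -> Direction:
        """Planted case-vs-control direction for ``assay`` in ``group``."""
        row = self.table[(self.table.assay_id == assay) & (self.table.group == group)]
        if row.empty:
            raise KeyError(assay)
        return Direction(row.iloc[0]["direction"])

    def fold_change(self, assay: str, group: str) -> float:
        row = self.table[(self.table.assay_id == assay) & (self.table.group == group)]
        if row.empty:
            raise KeyError((assay, group))
        return float(row.iloc[0]["fold_change"])


def ground_truth(config: SimulationConfig) -> GroundTruth:
    rows = []
    for a, spec in config.assays.items():
        sd = _bio_sd_cycles(spec.cv)
        for g in Group:
            fc = spec.fc(g)
            level = spec.control_mean * fc
            rows.append(
                {
                    "assay_id": a,
                    "group": g.value,
                    "mean_dct": _dct_mean(level, sd),
                    "mean_level": level,
                    "fold_change": fc,
                    "direction": (Direction.UP if fc >= 1 else Direction.DOWN).value,
                }
            )
    return GroundTruth(pd.DataFrame(rows))


def _sample_frame(config: SimulationConfig, rng: np.random.Generator) -> list[SampleRecord]:
    records = []
    for gname in sorted(config.group_sizes):
        group = Group(gname)
        n = config.group_sizes[gname]
        n_train = config.training_sizes.get(gname, 0)
        for i in range(n):
            phase = Phase.TRAINING if i < n_train else Phase.VALIDATION
            age = float(np.clip(rng.normal(45.0, 13.0), 18, 85))
            sex = "M" if rng.random() < 0.22 else "F"
            records.append(
                SampleRecord(f"{gname}-{i + 1:03d}", group, phase, age=round(age, 1), sex=sex)
            )
    return records


def _draw_true_dct(
    config: SimulationConfig, groups: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, list[str]]:
    """Biological (pre-measurement) dCT per sample x target assay."""
    assays = list(config.assays)
    n = groups.size
    out = np.empty((n, len(assays)))
    for j, a in enumerate(assays):
        spec = config.assays[a]
        sd = _bio_sd_cycles(spec.cv)
        mu = np.array([_dct_mean(spec.control_mean * spec.fc(Group(g)), sd) for g in groups])
        out[:, j] = mu + rng.normal(0.0, sd, size=n) if sd > 0 else mu
    return out, assays


def simulate_cohort(
    config: SimulationConfig, seed: int | None = None
) -> tuple[CtMatrix, list[SampleRecord], GroundTruth]:
    """Simulate the individual-sample (RT-qPCR) arm of a study.

    Reference CTs carry the per-sample input shift plus technical noise;
    target CTs add the biological dCT and their own technical noise;
    CTs above the censoring cutoff are reported as undetected.  The same
    config and seed always give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    records = _sample_frame(config, rng)
    sample_ids = [r.sample_id for r in records]
    groups = np.array([r.group.value for r in records])
    n = len(records)

    shift = rng.normal(config.ref_ct_mean, config.ref_ct_sd, size=n) if config.ref_ct_sd > 0 \
        else np.full(n, config.ref_ct_mean)
    refs = list(config.reference_assays)

    def tech(shape):
        return rng.normal(0.0, config.tech_sd, size=shape) if config.tech_sd > 0 \
            else np.zeros(shape)

    ref_ct = shift[:, None] + tech((n, len(refs)))
    true_dct, targets = _draw_true_dct(config, groups, rng)
    tgt_ct = shift[:, None] + true_dct + tech(true_dct.shape)

    ct = pd.DataFrame(
        np.hstack([ref_ct, tgt_ct]), index=sample_ids, columns=refs + targets
    )
    censored = ct > config.censor_cutoff
    ct = ct.mask(censored)
    n_rep = pd.DataFrame(1, index=ct.index, columns=ct.columns)
    matrix = CtMatrix(ct, censored, n_rep, max_cycles=config.censor_cutoff)
    return matrix, records, ground_truth(config)


def _null_assay_levels(n_extra: int) -> np.ndarray:
    """Deterministic spread of abundances for universe-padding assays:
    geometric ladder across the typical serum dynamic range."""
    if n_extra <= 0:
        return np.empty(0)
    return np.geomspace(2.0**-7, 2.0**2, n_extra)


def simulate_pools(
    config: SimulationConfig,
    pool_size: int | None = None,
    seed: int | None = None,
) -> dict[str, PoolProfile]:
    """Simulate the pooled screening arm (one pool per non-MTC group).

    Each pool mixes ``pool_size`` fresh members; the pooled linear
    abundance per assay is the mean of member 2^-dCT values, converted
    back to pool dCT = -log2(mean).  The screening universe is padded to
    ``config.screen_universe`` assays with null (fold change 1) assays
    on a fixed abundance ladder.
    """
    config.validate()
    pool_size = config.pool_size if pool_size is None else pool_size
    if pool_size <= 0:
        raise ValueError("pool size must be positive")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    assays = dict(config.assays)
    n_extra = config.screen_universe - len(assays) - len(config.reference_assays)
    for i, level in enumerate(_null_assay_levels(n_extra)):
        assays[f"miR-null-{i + 1:04d}"] = AssaySpec(control_mean=float(level), cv=0.5)
    padded = replace(config, assays=assays)

    profiles: dict[str, PoolProfile] = {}
    for gname in ("PTC", "BENIGN", "CONTROL"):
        group = Group(gname)
        members = [f"{gname}-pool-{i + 1:02d}" for i in range(pool_size)]
        true_dct, names = _draw_true_dct(
            padded, np.array([gname] * pool_size), rng
        )
        pooled_level = np.exp2(-true_dct).mean(axis=0)
        pool_dct = -np.log2(pooled_level)
        shift = rng.normal(config.ref_ct_mean, config.ref_ct_sd) if config.ref_ct_sd > 0 \
            else config.ref_ct_mean
        tech = rng.normal(0.0, config.tech_sd, size=len(names) + len(config.reference_assays)) \
            if config.tech_sd > 0 else np.zeros(len(names) + len(config.reference_assays))
        raw = pd.Series(
            np.concatenate([shift + tech[: len(config.reference_assays)],
                            shift + pool_dct + tech[len(config.reference_assays):]]),
            index=list(config.reference_assays) + names,
        )
        raw = raw.mask(raw > config.censor_cutoff)
        ref_ct = raw[list(config.reference_assays)].dropna()
        if ref_ct.empty:
            raise RuntimeError(f"pool {gname} lost all reference assays to censoring")
        norm = (raw - ref_ct.mean()).drop(list(config.reference_assays))
        profiles[gname] = PoolProfile(
            group=group, delta_ct=norm, raw_ct=raw.drop(list(config.reference_assays)),
            members=members,
        )
    return profiles


def _specs_from_table(table: dict, control_n: int, groups: tuple[str, ...]) -> dict[str, AssaySpec]:
    specs = {}
    for a, row in table.items():
        *means, control_sem = row
        control_mean = means[-1]
        cv = control_sem * math.sqrt(control_n) / control_mean
        fcs = {g: m / control_mean for g, m in zip(groups, means[:-1])}
        specs[a] = AssaySpec(control_mean=control_mean, cv=cv, fold_changes=fcs)
    return specs


def default_study_config() -> SimulationConfig:
    """The shipped study conditions: published group sizes, splits,
    panel effect sizes, SEM-derived CVs, two decoy assays and the
    aggressive-carcinoma fold changes for the three assayed miRNAs."""
    specs = _specs_from_table(PANEL_TABLE, control_n=57, groups=("PTC", "BENIGN"))
    for a, (mtc_mean, _b, _c, _s) in MTC_TABLE.items():
        spec = specs[a]
        fcs = dict(spec.fold_changes)
        fcs["MTC"] = mtc_mean / spec.control_mean
        specs[a] = AssaySpec(spec.control_mean, spec.cv, fcs)
    # low-abundance decoys: detected but with Cq mostly above 35,
    # exercising the low-expression exclusion
    for a in DECOY_ASSAYS:
        specs[a] = AssaySpec(control_mean=2.0**-11.5, cv=0.5, fold_changes={})
    return SimulationConfig(assays=specs)


def mtc_arm_config() -> SimulationConfig:
    """Matched-subset conditions for the aggressive-carcinoma arm:
    15/15/15 samples, three up-regulated miRNAs at their matched-table
    effect sizes."""
    specs = _specs_from_table(MTC_TABLE, control_n=MTC_N, groups=("MTC", "BENIGN"))
    return SimulationConfig(
        group_sizes={"MTC": MTC_N, "BENIGN": MTC_N, "CONTROL": MTC_N},
        training_sizes={},
        assays=specs,
    )


def null_config() -> SimulationConfig:
    """Same design as the default config but every fold change set to 1
    and no decoys: the no-signal calibration condition."""
    cfg = default_study_config()
    specs = {
        a: AssaySpec(s.control_mean, s.cv, {})
        for a, s in cfg.assays.items()
        if a not in DECOY_ASSAYS
    }
    return replace(cfg, assays=specs)
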