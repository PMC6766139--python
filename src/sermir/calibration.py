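"""Monte-Carlo calibration studies of the pipeline's decision rules.

These routines rerun the core analysis (normalization, training-phase
t tests, risk-model fitting, validation ROC) over many simulated
replicates to measure operating characteristics: the false-retention
rate under no signal, the null distribution of the panel AUC, and the
recovery rate of planted markers at the shipped effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import normalization, risk_score, roc
from .datamodel import Group, Phase
from .group_stats import students_t
from .simulate import SimulationConfig, null_config, simulate_cohort


@dataclass
class NullCalibration:
    n_reps: int
    retention_rate: dict[str, float]
    mean_panel_auc: float
    panel_auc_sd: float


def _phase_ids(records, group: Group, phase: Phase, keep: set[str]) -> list[str]:
    return [r.sample_id for r in records if r.group is group and r.phase is phase
            and r.sample_id in keep]


def null_calibration(
    n_reps: int = 2000,
    seed: int = 0,
    config: SimulationConfig | None = None,
    alpha: float = 0.05,
) -> NullCalibration:
    """No-signal calibration of the training retention rule and the
    panel AUC.

    Every replicate simulates the full study design with all fold
    changes at 1, runs the training-phase t test per miRNA (retention =
    p < alpha for case vs control), fits the risk model for the whole
    panel on the training set and scores the validation set.  A
    well-calibrated pipeline retains each null miRNA at rate ~alpha and
    produces validation panel AUCs centred on 1/2.
    """
    config = config or null_config()
    assays = list(config.assays)
    seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    retained = {a: 0 for a in assays}
    aucs = np.empty(n_reps)
    for i, s in enumerate(seeds):
        matrix, records, _ = simulate_cohort(config, seed=int(s))
        expr = normalization.normalize_matrix(matrix, config.reference_assays)
        keep = set(expr.sample_ids)
        tr_case = _phase_ids(records, Group.PTC, Phase.TRAINING, keep)
        tr_ctrl = _phase_ids(records, Group.CONTROL, Phase.TRAINING, keep)
        va_case = _phase_ids(records, Group.PTC, Phase.VALIDATION, keep)
        va_ctrl = _phase_ids(records, Group.CONTROL, Phase.VALIDATION, keep)
        for a in assays:
            res = students_t(
                expr.expression.loc[tr_case, a], expr.expression.loc[tr_ctrl, a]
            )
            if res.p_value < alpha:
                retained[a] += 1
        model = risk_score.build_risk_model(expr, tr_case, tr_ctrl, assays=assays)
        scored = risk_score.apply_risk_model(model, expr, va_case + va_ctrl)
        labels = np.array([1] * len(va_case) + [0] * len(va_ctrl))
        aucs[i] = roc.auc(scored.rsf.to_numpy(), labels)
    return NullCalibration(
        n_reps=n_reps,
        retention_rate={a: retained[a] / n_reps for a in assays},
        mean_panel_auc=float(aucs.mean()),
        panel_auc_sd=float(aucs.std(ddof=1)),
    )


@dataclass
class RecoveryResult:
    n_seeds: int
    retention_rate: dict[str, float]  # retained with the correct direction
    all_retained_rate: float
    panel_auc_gt_half_rate: float
    panel_ge_median_single_rate: float
    panel_aucs: list[float] = field(default_factory=list)


def recovery_study(
    n_seeds: int = 100,
    seed: int = 0,
    config: SimulationConfig | None = None,
    phase: str = "validation",
) -> RecoveryResult:
    """Recovery of planted panel miRNAs by the full pipeline at the
    shipped effect sizes, plus panel-vs-single AUC comparison per seed."""
    from . import pipeline as pl
    from .simulate import default_study_config

    config = config or default_study_config()
    planted = {
        a: ("UP" if spec.fc(Group.PTC) >= 1 else "DOWN")
        for a, spec in config.assays.items()
        if spec.fc(Group.PTC) != 1.0
    }
    seeds = np.random.SeedSequence(seed).generate_state(n_seeds) % (2**31)
    retained = {a: 0 for a in planted}
    n_all = n_gt = n_ge = 0
    panel_aucs = []
    for s in seeds:
        matrix, records, _ = simulate_cohort(config, seed=int(s))
        report = pl.run_pipeline(matrix, records, seed=int(s))
        ok = {
            a for a in report.training_retained
            if a in planted and report.directions.get(a) == planted[a]
        }
        for a in ok:
            retained[a] += 1
        if len(ok) == len(planted):
            n_all += 1
        panel = report.panel_roc.get(phase, {}).get("PTC vs CONTROL")
        singles = [
            v["auc"] for k, v in report.single_roc.get(phase, {}).items()
            if k.endswith("|PTC vs CONTROL")
        ]
        if panel and singles:
            panel_aucs.append(panel["auc"])
            if panel["auc"] > 0.5:
                n_gt += 1
            if panel["auc"] >= float(np.median(singles)):
                n_ge += 1
    return RecoveryResult(
        n_seeds=n_seeds,
        retention_rate={a: retained[a] / n_seeds for a in planted},
        all_retained_rate=n_all / n_seeds,
        panel_auc_gt_half_rate=n_gt / n_seeds,
        panel_ge_median_single_rate=n_ge / n_seeds,
        panel_aucs=panel_aucs,
    )


@dataclass
class MtcArmStudy:
    n_seeds: int
    median_panel_auc_vs_control: float
    median_panel_auc_vs_benign: float
    median_single_aucs: dict[str, float]


def mtc_arm_study(
    n_seeds: int = 200,
    seed: int = 0,
    config: SimulationConfig | None = None,
    assays: tuple[str, ...] = ("miR-222-3p", "miR-17-5p"),
) -> MtcArmStudy:
    """Repeated simulation of the aggressive-carcinoma arm (matched
    15/15/15 subsets): distribution of the two-marker panel AUC against
    controls and against benign nodules."""
    from . import pipeline as pl
    from .simulate import mtc_arm_config

    config = config or mtc_arm_config()
    pcfg = pl.PipelineConfig(mtc_assays=assays, mtc_subset_size=config.group_sizes["BENIGN"])
    seeds = np.random.SeedSequence(seed).generate_state(n_seeds) % (2**31)
    vs_control, vs_benign = [], []
    singles: dict[str, list[float]] = {a: [] for a in assays}
    for s in seeds:
        matrix, records, _ = simulate_cohort(config, seed=int(s))
        expr = normalization.normalize_matrix(matrix, config.reference_assays)
        out = pl.mtc_arm(expr, records, pcfg)
        vs_control.append(out["panel"]["MTC vs CONTROL"]["auc"])
        vs_benign.append(out["panel"]["MTC vs BENIGN"]["auc"])
        for a in assays:
            singles[a].append(out["single"][f"{a}|MTC vs CONTROL"]["auc"])
    return MtcArmStudy(
        n_seeds=n_seeds,
        median_panel_auc_vs_control=float(np.median(vs_control)),
        median_panel_auc_vs_benign=float(np.median(vs_benign)),
        median_single_aucs={a: float(np.median(v)) for a, v in singles.items()},
    )
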