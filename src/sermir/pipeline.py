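"""Multiphase study orchestration.

Stage order mirrors the study design: pooled screening (when pool data
is present) -> training-phase confirmation (low-expression exclusion,
per-miRNA t tests, direction calls) -> risk-model fitting on the
training set -> frozen-model validation with per-miRNA and panel ROC ->
combined-set ROC -> aggressive-carcinoma (MTC) arm on the up-regulated
markers with matched subsets.

The candidate set for the individual-sample phases is taken from the
assays present in the individual-sample CT table: in the underlying
two-technology design the qPCR plate is only ever loaded with the
curated candidates, so the table's columns *are* the candidate list.
Set ``restrict_to_screen`` to additionally intersect with the pool
screening decision when both arms share an assay universe.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import group_stats, normalization, risk_score, roc, screening
from .datamodel import CtMatrix, Direction, ExpressionMatrix, Group, Phase, SampleRecord
from .io import validate_design

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    reference_assays: tuple[str, ...] = ("let-7d", "let-7g", "let-7i")
    ct_cutoff: float = 28.0
    fc_cutoff: float = 5.0
    whitelist: set[str] = field(default_factory=set)
    restrict_to_screen: bool = False
    cq_cutoff: float = 35.0
    max_censored_fraction: float = 0.5
    retention_comparisons: list[tuple[str, str]] = field(
        default_factory=lambda: [("PTC", "CONTROL")]
    )
    retention_mode: str = "all"  # "all" or "any" of the comparisons
    retention_alpha: float = 0.05
    test_scale: str = "expression"  # "expression" (2^-dCT) or "dct"
    roc_comparisons: list[tuple[str, str]] = field(
        default_factory=lambda: [("PTC", "CONTROL"), ("PTC", "BENIGN"), ("BENIGN", "CONTROL")]
    )
    ci_method: str = "delong"
    down_rule: str = "below_lower"
    fit_on: str = "training"  # or "combined": fit the panel on all samples
    mtc_assays: tuple[str, ...] = ("miR-222-3p", "miR-17-5p", "miR-451a")
    mtc_subset_size: int = 15

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["whitelist"] = sorted(self.whitelist)
        d["retention_comparisons"] = [list(c) for c in self.retention_comparisons]
        d["roc_comparisons"] = [list(c) for c in self.roc_comparisons]
        d["reference_assays"] = list(self.reference_assays)
        d["mtc_assays"] = list(self.mtc_assays)
        return d


def _roc_summary(r: roc.RocResult) -> dict:
    return {
        "comparison": r.comparison,
        "auc": r.auc,
        "ci_low": r.ci[0],
        "ci_high": r.ci[1],
        "n_case": r.n_case,
        "n_control": r.n_control,
        "flipped": r.flipped,
        "ci_method": r.ci_method,
        "flags": r.flags,
    }


@dataclass
class PipelineReport:
    screening: pd.DataFrame | None
    excluded_low_expression: dict[str, float]
    training_tests: pd.DataFrame
    training_retained: list[str]
    directions: dict[str, str]
    model: risk_score.RiskModel | None
    single_roc: dict[str, dict[str, dict]]  # phase -> "assay|comparison" -> summary
    panel_roc: dict[str, dict[str, dict]]  # phase -> comparison -> summary
    mtc: dict | None
    manifest: dict

    def to_json(self, path=None) -> str:
        payload = {
            "screening": None
            if self.screening is None
            else json.loads(self.screening.to_json(orient="index")),
            "excluded_low_expression": self.excluded_low_expression,
            "training_tests": json.loads(self.training_tests.to_json(orient="records")),
            "training_retained": self.training_retained,
            "directions": self.directions,
            "model": None if self.model is None else json.loads(self.model.to_json()),
            "single_roc": self.single_roc,
            "panel_roc": self.panel_roc,
            "mtc": self.mtc,
            "manifest": self.manifest,
        }
        text = json.dumps(payload, indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def _ids(records: list[SampleRecord], group: Group, phase: Phase | None = None) -> list[str]:
    return [
        r.sample_id
        for r in records
        if r.group is group and (phase is None or r.phase is phase)
    ]


def _scores(expr: ExpressionMatrix, assay: str, ids, scale: str) -> np.ndarray:
    frame = expr.expression if scale == "expression" else expr.delta_ct
    return frame.loc[ids, assay].to_numpy(dtype=float)


def run_pipeline(
    matrix: CtMatrix,
    records: list[SampleRecord],
    config: PipelineConfig | None = None,
    pools: dict[str, object] | None = None,
    seed: int | None = None,
) -> PipelineReport:
    """Execute every stage on an individual-sample CT matrix (plus
    optional pooled screening profiles) and return the structured
    report.  Reruns with the same inputs and seed are byte-identical."""
    config = config or PipelineConfig()

    report_design = validate_design(matrix, records, reference_assays=config.reference_assays)
    if not report_design.ok:
        raise StageError("validate", "; ".join(report_design.fatal))

    screen_table = None
    screen_candidates: set[str] | None = None
    if pools:
        try:
            case = pools["PTC"]
            comparators = [pools[g] for g in ("BENIGN", "CONTROL") if g in pools]
            rep = screening.screen_candidates(
                case, comparators, config.ct_cutoff, config.fc_cutoff, config.whitelist
            )
            screen_table = rep.table
            screen_candidates = set(rep.candidates)
        except Exception as exc:  # noqa: BLE001 - re-tag with the stage
            raise StageError("screen", str(exc)) from exc

    try:
        expr = normalization.normalize_matrix(matrix, config.reference_assays)
    except Exception as exc:
        raise StageError("normalize", str(exc)) from exc

    by_phase = {p: [r for r in records if r.phase is p] for p in Phase}
    train_ids = [r.sample_id for r in by_phase[Phase.TRAINING] if r.sample_id in expr.sample_ids]
    if not train_ids:
        raise StageError("training", "no training-phase samples")

    # low-expression exclusion on the training CT values
    targets = [a for a in matrix.assay_ids if a not in set(config.reference_assays)]
    if config.restrict_to_screen and screen_candidates is not None:
        targets = [a for a in targets if a in screen_candidates]
    excl = group_stats.low_expression_filter(
        matrix.subset_samples(train_ids),
        cq_cutoff=config.cq_cutoff,
        max_fraction=config.max_censored_fraction,
        assays=targets,
    )

    # per-miRNA two-group tests on the training set
    rows = []
    retained = []
    case_group = Group(config.retention_comparisons[0][0])
    ctrl_group = Group(config.retention_comparisons[0][1])
    for assay in excl.retained:
        passes = []
        for ga, gb in config.retention_comparisons:
            ids_a = _ids(records, Group(ga), Phase.TRAINING)
            ids_b = _ids(records, Group(gb), Phase.TRAINING)
            ids_a = [i for i in ids_a if i in expr.sample_ids]
            ids_b = [i for i in ids_b if i in expr.sample_ids]
            try:
                res = group_stats.students_t(
                    _scores(expr, assay, ids_a, config.test_scale),
                    _scores(expr, assay, ids_b, config.test_scale),
                    comparison=f"{ga} vs {gb}",
                )
            except ValueError as exc:
                raise StageError("training", f"{assay}: {exc}") from exc
            rows.append(
                {"assay_id": assay, "comparison": res.comparison,
                 "t": res.statistic, "df": res.df, "p": res.p_value}
            )
            passes.append(res.p_value < config.retention_alpha)
        ok = all(passes) if config.retention_mode == "all" else any(passes)
        if ok:
            retained.append(assay)
    training_tests = pd.DataFrame(rows, columns=["assay_id", "comparison", "t", "df", "p"])
    log.info("training: %d/%d assays retained", len(retained), len(excl.retained))

    train_case = [i for i in _ids(records, case_group, Phase.TRAINING) if i in expr.sample_ids]
    train_ctrl = [i for i in _ids(records, ctrl_group, Phase.TRAINING) if i in expr.sample_ids]
    directions = risk_score.determine_directions(expr, train_case, train_ctrl, retained)

    model = None
    if retained:
        if config.fit_on == "combined":
            fit_case = [i for i in _ids(records, case_group) if i in expr.sample_ids]
            fit_ctrl = [i for i in _ids(records, ctrl_group) if i in expr.sample_ids]
        else:
            fit_case, fit_ctrl = train_case, train_ctrl
        model = risk_score.build_risk_model(
            expr, fit_case, fit_ctrl, directions=directions,
            assays=retained, down_rule=config.down_rule,
        )

    # ROC per phase: validation set, and training+validation combined
    phases = {"validation": Phase.VALIDATION, "combined": None}
    single_roc: dict[str, dict[str, dict]] = {}
    panel_roc: dict[str, dict[str, dict]] = {}
    scored = risk_score.apply_risk_model(model, expr) if model else None
    for phase_name, phase in phases.items():
        single_roc[phase_name] = {}
        panel_roc[phase_name] = {}
        for ga, gb in config.roc_comparisons:
            ids_a = [i for i in _ids(records, Group(ga), phase) if i in expr.sample_ids]
            ids_b = [i for i in _ids(records, Group(gb), phase) if i in expr.sample_ids]
            if len(ids_a) < 2 or len(ids_b) < 2:
                continue
            comp = f"{ga} vs {gb}"
            labels = np.array([1] * len(ids_a) + [0] * len(ids_b))
            for assay in retained:
                vals = np.concatenate(
                    [_scores(expr, assay, ids_a, "expression"),
                     _scores(expr, assay, ids_b, "expression")]
                )
                finite = np.isfinite(vals)
                r = roc.roc_analysis(
                    vals[finite], labels[finite], comparison=comp, ci_method=config.ci_method
                )
                single_roc[phase_name][f"{assay}|{comp}"] = _roc_summary(r)
            if scored is not None:
                vals = scored.rsf.loc[ids_a + ids_b].to_numpy()
                r = roc.roc_analysis(
                    vals, labels, comparison=comp, ci_method=config.ci_method, orient=False
                )
                panel_roc[phase_name][comp] = _roc_summary(r)

    mtc = None
    if any(r.group is Group.MTC for r in records) and any(
        a in expr.assay_ids for a in config.mtc_assays
    ):
        mtc = mtc_arm(expr, records, config)

    manifest = {"seed": seed, "config": config.to_dict(), "n_samples": len(records)}
    return PipelineReport(
        screening=screen_table,
        excluded_low_expression=excl.excluded,
        training_tests=training_tests,
        training_retained=retained,
        directions={a: d.value for a, d in directions.items()},
        model=model,
        single_roc=single_roc,
        panel_roc=panel_roc,
        mtc=mtc,
        manifest=manifest,
    )


def mtc_arm(
    expr: ExpressionMatrix,
    records: list[SampleRecord],
    config: PipelineConfig | None = None,
) -> dict:
    """Aggressive-carcinoma arm: score the up-regulated miRNAs on all
    MTC samples against matched benign/control subsets.

    Matching is emulated by taking the first ``mtc_subset_size``
    validation-phase benign and control samples (the generator already
    draws matched demographics).  The risk model for the two-marker
    panel is fitted MTC vs control and applied unchanged to both
    comparisons.
    """
    config = config or PipelineConfig()
    assays = [a for a in config.mtc_assays if a in expr.assay_ids]
    if not assays:
        raise StageError("mtc", "none of the MTC-arm assays present")
    mtc_ids = [i for i in _ids(records, Group.MTC) if i in expr.sample_ids]
    if len(mtc_ids) < 2:
        raise StageError("mtc", "need at least two MTC samples")

    def subset(group: Group) -> list[str]:
        ids = [i for i in _ids(records, group, Phase.VALIDATION) if i in expr.sample_ids]
        if not ids:  # designs without an explicit validation phase
            ids = [i for i in _ids(records, group) if i in expr.sample_ids]
        return ids[: config.mtc_subset_size]

    benign_ids, control_ids = subset(Group.BENIGN), subset(Group.CONTROL)
    directions = risk_score.determine_directions(expr, mtc_ids, control_ids, assays)
    model = risk_score.build_risk_model(
        expr, mtc_ids, control_ids, directions=directions,
        assays=assays, down_rule=config.down_rule,
    )
    scored = risk_score.apply_risk_model(model, expr)

    out: dict = {"assays": assays, "single": {}, "panel": {}}
    for comp_name, other in (("MTC vs CONTROL", control_ids), ("MTC vs BENIGN", benign_ids)):
        if len(other) < 2:
            continue
        labels = np.array([1] * len(mtc_ids) + [0] * len(other))
        for assay in assays:
            vals = np.concatenate(
                [_scores(expr, assay, mtc_ids, "expression"),
                 _scores(expr, assay, other, "expression")]
            )
            finite = np.isfinite(vals)
            r = roc.roc_analysis(
                vals[finite], labels[finite], comparison=comp_name, ci_method=config.ci_method
            )
            out["single"][f"{assay}|{comp_name}"] = _roc_summary(r)
        vals = scored.rsf.loc[mtc_ids + other].to_numpy()
        r = roc.roc_analysis(
            vals, labels, comparison=comp_name, ci_method=config.ci_method, orient=False
        )
        out["panel"][comp_name] = _roc_summary(r)
    out["model"] = json.loads(model.to_json())
    return out


def compare_panels(report: PipelineReport, phase: str = "validation") -> pd.DataFrame:
    """Tabulate panel AUC against the single-miRNA AUCs per comparison."""
    rows = []
    for comp, panel in report.panel_roc.get(phase, {}).items():
        singles = [
            v["auc"]
            for key, v in report.single_roc.get(phase, {}).items()
            if key.endswith(f"|{comp}")
        ]
        if not singles:
            continue
        rows.append(
            {
                "comparison": comp,
                "panel_auc": panel["auc"],
                "best_single_auc": max(singles),
                "median_single_auc": float(np.median(singles)),
                "panel_beats_best": panel["auc"] >= max(singles),
                "panel_beats_median": panel["auc"] >= float(np.median(singles)),
            }
        )
    return pd.DataFrame(rows)
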