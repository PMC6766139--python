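"""Synthetic-study generator: determinism, noise-free limits, fidelity."""

import dataclasses

import numpy as np
import pytest

from sermir import io, simulate
from sermir.datamodel import Group, Phase
from sermir.normalization import normalize_matrix


def noise_free(config: simulate.SimulationConfig) -> simulate.SimulationConfig:
    assays = {
        a: simulate.AssaySpec(s.control_mean, 0.0, dict(s.fold_changes))
        for a, s in config.assays.items()
    }
    return dataclasses.replace(config, assays=assays, ref_ct_sd=0.0, tech_sd=0.0)


def small_config(**assays) -> simulate.SimulationConfig:
    return simulate.SimulationConfig(
        group_sizes={"PTC": 8, "CONTROL": 8},
        training_sizes={"PTC": 4, "CONTROL": 4},
        assays={k: simulate.AssaySpec(**v) for k, v in assays.items()},
    )


def test_same_seed_gives_identical_bytes(tmp_path):
    cfg = simulate.default_study_config()
    paths = []
    for name in ("a.csv", "b.csv"):
        matrix, records, _ = simulate.simulate_cohort(cfg, seed=11)
        p = tmp_path / name
        io.write_ct_table(p, matrix, records)
        paths.append(p)
    assert paths[0].read_bytes() == paths[1].read_bytes()
    m1, _, _ = simulate.simulate_cohort(cfg, seed=11)
    m2, _, _ = simulate.simulate_cohort(cfg, seed=12)
    assert not m1.ct.equals(m2.ct)  # different seed, different data


def test_noise_free_limit_recovers_planted_shift_exactly():
    cfg = noise_free(small_config(m=dict(control_mean=0.5, cv=0.3, fold_changes={"PTC": 4.0})))
    matrix, records, truth = simulate.simulate_cohort(cfg, seed=0)
    expr = normalize_matrix(matrix)
    ptc = [r.sample_id for r in records if r.group is Group.PTC]
    ctrl = [r.sample_id for r in records if r.group is Group.CONTROL]
    dct_case = expr.delta_ct.loc[ptc, "m"].to_numpy()
    dct_ctrl = expr.delta_ct.loc[ctrl, "m"].to_numpy()
    # a 4-fold planted shift is exactly 2 cycles
    assert np.allclose(dct_ctrl - dct_case, 2.0, atol=1e-12)
    fc = 2.0 ** -(dct_case.mean() - dct_ctrl.mean())
    assert fc == pytest.approx(truth.fold_change("m", "PTC"), rel=1e-12)


def test_effect_size_fidelity_at_large_n():
    """Generated biological group means converge to the configured
    means (2%).  Technical noise is off here: it inflates the measured
    (normalized) mean by a further ~e^((ln2 sd)^2 (1+1/3)/2) - 1 ~ 2%,
    which is a measurement property, not a generator bias."""
    cfg = simulate.SimulationConfig(
        group_sizes={"PTC": 5000, "CONTROL": 5000},
        training_sizes={},
        tech_sd=0.0,
        assays={"m": simulate.AssaySpec(control_mean=0.29, cv=0.52, fold_changes={"PTC": 1.43})},
    )
    matrix, records, _ = simulate.simulate_cohort(cfg, seed=5)
    expr = normalize_matrix(matrix)
    groups = {g: [r.sample_id for r in records if r.group is g] for g in (Group.PTC, Group.CONTROL)}
    ctrl_mean = expr.expression.loc[groups[Group.CONTROL], "m"].mean()
    ptc_mean = expr.expression.loc[groups[Group.PTC], "m"].mean()
    assert ctrl_mean == pytest.approx(0.29, rel=0.02)
    assert ptc_mean == pytest.approx(0.29 * 1.43, rel=0.02)


def test_default_config_matches_study_conditions():
    cfg = simulate.default_study_config()
    assert cfg.group_sizes == {"PTC": 100, "BENIGN": 91, "MTC": 15, "CONTROL": 89}
    assert cfg.training_sizes == {"PTC": 36, "BENIGN": 36, "CONTROL": 32}
    assert cfg.assays["miR-222-3p"].control_mean == 0.29
    assert cfg.assays["miR-222-3p"].fc(Group.MTC) * 0.29 == pytest.approx(0.731)
    assert cfg.screen_universe == 756
    # six panel miRNAs + two low-abundance decoys
    assert len(cfg.assays) == 8
    matrix, records, _ = simulate.simulate_cohort(cfg, seed=0)
    counts = {}
    for r in records:
        counts[(r.phase, r.group)] = counts.get((r.phase, r.group), 0) + 1
    assert counts[(Phase.TRAINING, Group.PTC)] == 36
    assert counts[(Phase.VALIDATION, Group.PTC)] == 64
    assert counts[(Phase.VALIDATION, Group.CONTROL)] == 57


def test_generated_group_mean_consistent_with_config():
    """Sample mean of 2^-dCT for miR-222-3p lands within 3 SEM of the
    configured group mean under the default conditions."""
    cfg = simulate.default_study_config()
    matrix, records, _ = simulate.simulate_cohort(cfg, seed=7)
    expr = normalize_matrix(matrix)
    ids = [r.sample_id for r in records if r.group is Group.CONTROL]
    vals = expr.expression.loc[ids, "miR-222-3p"].dropna()
    sem = vals.std(ddof=1) / np.sqrt(len(vals))
    assert abs(vals.mean() - 0.29) <= 3 * sem


def test_decoys_mostly_above_cq35():
    cfg = simulate.default_study_config()
    matrix, _, _ = simulate.simulate_cohort(cfg, seed=3)
    for decoy in simulate.DECOY_ASSAYS:
        ct = matrix.ct[decoy]
        high = (~np.isfinite(ct)) | (ct > 35.0)
        assert high.mean() > 0.5


def test_invalid_config_names_offending_field():
    cfg = small_config(m=dict(control_mean=0.5, cv=0.3))
    cfg.ref_ct_sd = -1.0
    with pytest.raises(ValueError, match="ref_ct_sd"):
        cfg.validate()
    cfg = small_config(m=dict(control_mean=-2.0, cv=0.3))
    with pytest.raises(ValueError, match="control_mean"):
        simulate.simulate_cohort(cfg, seed=0)
    cfg = small_config(m=dict(control_mean=0.5, cv=0.3))
    cfg.training_sizes = {"PTC": 99}
    with pytest.raises(ValueError, match="training size"):
        cfg.validate()


def test_pool_of_identical_samples_has_common_delta_ct():
    cfg = noise_free(small_config(m=dict(control_mean=0.5, cv=0.0)))
    pools = simulate.simulate_pools(cfg, pool_size=5, seed=1)
    # bio noise zero: every member shares dCT = -log2(0.5) = 1
    assert pools["CONTROL"].delta_ct["m"] == pytest.approx(1.0, abs=1e-12)


def test_pools_pad_universe_and_record_members():
    cfg = simulate.default_study_config()
    pools = simulate.simulate_pools(cfg, seed=2)
    prof = pools["PTC"]
    assert len(prof.delta_ct) == 756 - len(cfg.reference_assays)
    assert len(prof.members) == cfg.pool_size
    assert prof.group is Group.PTC
    with pytest.raises(ValueError, match="pool size"):
        simulate.simulate_pools(cfg, pool_size=0)


def test_planted_pool_fold_change_recovered_at_low_noise():
    """A 5-fold planted miRNA shows a pool fold change in [4, 6]."""
    hits = 0
    n_seeds = 30
    for seed in range(n_seeds):
        cfg = small_config(
            m=dict(control_mean=0.5, cv=0.1, fold_changes={"PTC": 5.0})
        )
        cfg.tech_sd = 0.05
        cfg.screen_universe = 10
        pools = simulate.simulate_pools(cfg, pool_size=20, seed=seed)
        fc = 2.0 ** -(pools["PTC"].delta_ct["m"] - pools["CONTROL"].delta_ct["m"])
        if 4.0 <= fc <= 6.0:
            hits += 1
    assert hits == n_seeds
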