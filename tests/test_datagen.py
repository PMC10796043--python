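"""The synthetic world: determinism, design invariants, ground truth."""

import numpy as np
import pandas as pd
import pytest

from hetforest import datagen
from hetforest.datagen import (ConfigError, CovariateDef, DGPConfig, EffectDef,
                               OutcomeDef, SchemaError, default_config,
                               generate_sample, make_subgroups, true_cate)


def _logit(p):
    return float(np.log(p / (1 - p)))


def test_identical_config_and_seed_reproduce_sample(simple_config):
    s1, t1 = generate_sample(simple_config, 42)
    s2, t2 = generate_sample(simple_config, 42)
    pd.testing.assert_frame_equal(s1.df, s2.df)
    np.testing.assert_array_equal(t1.tau["y"], t2.tau["y"])
    s3, _ = generate_sample(simple_config, 43)
    assert not s1.df.equals(s3.df)


def test_zero_effect_no_crossover_forces_controls_untreated(simple_config):
    simple_config.outcomes[0].effect = EffectDef("constant", value=0.0)
    simple_config.n_households = 100
    sample, truth = generate_sample(simple_config, 1)
    assert (sample.D[sample.Z == 0] == 0).all()
    assert (truth.tau["y"] == 0).all()


def test_funnel_consistency_and_crossover_rates():
    cfg = default_config(n_households=10_000)
    cfg.apply_coefs = {"intercept": _logit(0.64)}
    cfg.approve_coefs = {"intercept": _logit(0.478)}
    sample, _ = generate_sample(cfg, 3)
    z1 = sample.Z == 1
    n1 = int(z1.sum())
    uptake = sample.D[z1].mean()
    expected = 0.64 * 0.478
    assert abs(uptake - expected) < 3 * np.sqrt(expected * (1 - expected) / n1)
    # funnel identity: P(D|Z=1) = P(applied|Z=1) * P(approved|applied)
    p_app = sample.applied[z1].mean()
    p_apr = sample.approved[sample.applied == 1].mean()
    assert abs(uptake - p_app * p_apr) < 1e-12  # exact by construction
    # control crossover
    z0 = ~z1
    c = sample.D[z0].mean()
    assert abs(c - cfg.control_crossover) < 3 * np.sqrt(0.02 * 0.98 / z0.sum())


def test_households_share_lottery_draw(default_sample):
    _, sample, _ = default_sample
    assert (sample.df.groupby("household_id")["Z"].nunique() == 1).all()


def test_default_marginals_match_study_prevalences():
    cfg = default_config(n_households=20_000)
    sample, _ = generate_sample(cfg, 11)
    df = sample.df
    assert abs(df.cov_female.mean() - 0.56) < 0.02
    assert abs(df.cov_race_white.mean() - 0.69) < 0.02
    assert abs(df.cov_depression.mean() - 0.34) < 0.02
    assert len(sample.covariate_names) == 19


def test_true_cate_constant_step_linear():
    covs = [CovariateDef("white", p=0.5), CovariateDef("age49", p=0.3)]
    X = pd.DataFrame({"white": [1, 0], "age49": [0, 1]})
    base = dict(n_households=10, covariates=covs, control_crossover=0.0)

    cfg = DGPConfig(outcomes=[OutcomeDef("y", effect=EffectDef("constant", value=2.0))], **base)
    np.testing.assert_array_equal(true_cate(cfg, X, "y"), [2.0, 2.0])

    cfg = DGPConfig(outcomes=[OutcomeDef("y", effect=EffectDef(
        "step", on="white", value_if=1.0, value_else=3.0))], **base)
    np.testing.assert_array_equal(true_cate(cfg, X, "y"), [1.0, 3.0])

    cfg = DGPConfig(outcomes=[OutcomeDef("y", effect=EffectDef(
        "linear", intercept=0.5, coefs={"age49": 2.0}))], **base)
    # hand evaluation of a + b * indicator on the enumerated grid
    np.testing.assert_allclose(true_cate(cfg, X, "y"), [0.5, 2.5])

    cfg = DGPConfig(outcomes=[OutcomeDef("y", effect=EffectDef(
        "linear", coefs={"nope": 1.0}))], **base)
    with pytest.raises(ConfigError, match="nope"):
        true_cate(cfg, X, "y")


def test_invalid_probability_raises_named_error(simple_config):
    simple_config.p_select = 1.7
    with pytest.raises(ConfigError, match="p_select"):
        generate_sample(simple_config, 0)


def test_subgroup_masks_partition_and_count(default_sample):
    _, sample, _ = default_sample
    masks = make_subgroups(sample)
    assert len(masks) == 22  # overall + 21 prespecified subgroups
    assert masks["overall"].all()
    np.testing.assert_array_equal(masks["males"] | masks["females"], masks["overall"])
    assert not (masks["males"] & masks["females"]).any()
    age_union = masks["age_19_34"] | masks["age_35_49"] | masks["age_50_64"]
    np.testing.assert_array_equal(age_union, masks["overall"])
    sex_age = np.zeros(sample.n, dtype=bool)
    for k, m in masks.items():
        if "_males" in k or "_females" in k:
            if k.startswith("age_"):
                sex_age |= m
    np.testing.assert_array_equal(sex_age, masks["overall"])


def test_subgroup_masks_hand_records():
    cfg = default_config(n_households=4)
    sample, _ = generate_sample(cfg, 0)
    df = sample.df.iloc[:4].copy()
    df["cov_age_19_34"], df["cov_age_35_49"], df["cov_age_50_64"] = [1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 1]
    df["cov_female"] = [1, 0, 1, 0]
    df["cov_race_white"] = [1, 1, 0, 0]
    df["cov_depression"] = [0, 0, 1, 0]
    for c in ("cov_diabetes", "cov_hypertension", "cov_cholesterol",
              "cov_heart_attack", "cov_chf"):
        df[c] = 0
    df["cov_diabetes"] = [1, 0, 0, 0]
    small = datagen.ObservationalSample(df=df.reset_index(drop=True),
                                        covariate_names=sample.covariate_names,
                                        outcome_names=sample.outcome_names)
    masks = make_subgroups(small)
    np.testing.assert_array_equal(masks["females"], [True, False, True, False])
    np.testing.assert_array_equal(masks["white_males"], [False, True, False, False])
    np.testing.assert_array_equal(masks["age_50_64_males"], [False, False, False, True])
    np.testing.assert_array_equal(masks["high_risk"], [True, False, False, False])
    np.testing.assert_array_equal(masks["depressed"], [False, False, True, False])


def test_missing_label_columns_raise_schema_error(simple_config):
    sample, _ = generate_sample(simple_config, 1)
    with pytest.raises(SchemaError, match="missing"):
        make_subgroups(sample)


def test_config_json_round_trip():
    cfg = default_config(n_households=50)
    cfg2 = DGPConfig.from_json(cfg.to_json())
    assert cfg2.to_json() == cfg.to_json()
    s1, _ = generate_sample(cfg, 9)
    s2, _ = generate_sample(cfg2, 9)
    pd.testing.assert_frame_equal(s1.df, s2.df)


def test_compliance_prob_matches_empirical_uptake_gap():
    cfg = default_config(n_households=8000)
    sample, truth = generate_sample(cfg, 21)
    emp = sample.D[sample.Z == 1].mean() - sample.D[sample.Z == 0].mean()
    model = truth.compliance_prob.mean()
    assert abs(emp - model) < 3 * np.sqrt(0.3 * 0.7 / (sample.Z == 1).sum()) * 2
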