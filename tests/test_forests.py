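"""Honest forests: regression nuisances, causal trees, prediction contracts."""

import numpy as np
import pytest

from conftest import make_centered_toy
from hetforest import studies
from hetforest.datagen import generate_sample
from hetforest.forests import (CausalForest, ForestParams, InstrumentalForest,
                               RegressionForest, center_sample, grow_causal_tree,
                               NuisanceFit, variable_importance)


# ---------------------------------------------------------------------------
# regression forests
# ---------------------------------------------------------------------------

def test_regression_forest_constant_response_predicts_constant():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(200, 3))
    res = RegressionForest(X, np.full(200, 3.25),
                           params=ForestParams(n_trees=20, seed=1)).fit()
    np.testing.assert_allclose(res.predict(rng.normal(size=(10, 3))), 3.25)
    oob = res.predict_oob()
    np.testing.assert_allclose(oob[np.isfinite(oob)], 3.25)


def test_regression_forest_recovers_noiseless_step():
    rng = np.random.default_rng(1)
    n = 500
    X = np.column_stack([rng.integers(0, 2, n), rng.normal(size=n)])
    y = np.where(X[:, 0] == 1, 2.0, -1.0)
    res = RegressionForest(X, y, params=ForestParams(n_trees=60, seed=2)).fit()
    oob = res.predict_oob()
    k = np.isfinite(oob)
    np.testing.assert_allclose(oob[k], y[k], atol=1e-6)


def test_regression_forest_propensity_under_randomization(simple_config):
    sample, _ = generate_sample(simple_config, 5)
    res = RegressionForest(sample.X, sample.Z, sample.weight, sample.household_id,
                           params=ForestParams(n_trees=60, seed=3)).fit()
    e = res.predict_oob()
    k = np.isfinite(e)
    se = np.sqrt(0.25 / k.sum())
    assert abs(e[k].mean() - 0.5) < 3 * se * 3  # conservative: household clustering


def test_full_sample_fraction_leaves_no_oob_predictions():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(80, 2))
    y = rng.normal(size=80)
    res = RegressionForest(X, y, params=ForestParams(
        n_trees=10, sample_fraction=1.0, seed=5)).fit()
    assert np.isnan(res.predict_oob()).all()


def test_oob_determinism_and_nan_rejection():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(100, 2))
    y = rng.normal(size=100)
    r1 = RegressionForest(X, y, params=ForestParams(n_trees=15, seed=9)).fit()
    r2 = RegressionForest(X, y, params=ForestParams(n_trees=15, seed=9)).fit()
    np.testing.assert_array_equal(r1.predict_oob(), r2.predict_oob())
    y_bad = y.copy()
    y_bad[3] = np.nan
    with pytest.raises(ValueError, match="missing"):
        RegressionForest(X, y_bad)


# ---------------------------------------------------------------------------
# centering
# ---------------------------------------------------------------------------

def test_center_sample_arithmetic():
    nui = NuisanceFit(m_hat=np.array([2.0]), e_hat=np.array([0.25]),
                      e_hat_raw=np.array([0.25]))
    yc, zc, _, keep = center_sample(np.array([3.0]), np.array([1.0]), nui)
    assert yc[0] == 1.0 and zc[0] == 0.75 and keep.all()

    nui0 = NuisanceFit(m_hat=np.zeros(4), e_hat=np.full(4, 0.5),
                       e_hat_raw=np.full(4, 0.5))
    y = np.array([1.0, 2, 3, 4])
    z = np.array([0.0, 1, 0, 1])
    yc, zc, _, _ = center_sample(y, z, nui0)
    np.testing.assert_array_equal(yc, y)
    np.testing.assert_array_equal(zc, z - 0.5)


# ---------------------------------------------------------------------------
# single honest causal trees
# ---------------------------------------------------------------------------

def test_causal_tree_splits_noiseless_two_group_effects():
    # 16 points, one binary covariate, noise-free effects +2 / -2 by group,
    # both arms and both groups present in each honest half
    X = np.repeat([0.0, 1.0], 8)[:, None]
    treat = np.tile([0, 1], 8).astype(np.int64)
    zc = treat - 0.5
    yc = np.where(X[:, 0] == 1, 2.0, -2.0) * zc
    w = np.ones(16)
    s_idx = np.concatenate([np.arange(0, 4), np.arange(8, 12)])
    e_idx = np.concatenate([np.arange(4, 8), np.arange(12, 16)])
    tree = grow_causal_tree(X, yc, zc, w, treat, s_idx, e_idx,
                            params=ForestParams(min_node_size=1, mtry=1), seed=0)
    assert tree.root_split() is not None and tree.root_split()[0] == 0
    leaf_lo = tree.leaf_for(np.array([0.0]))
    leaf_hi = tree.leaf_for(np.array([1.0]))
    assert abs(tree.value[leaf_hi] - 2.0) < 1e-6
    assert abs(tree.value[leaf_lo] + 2.0) < 1e-6


def test_constant_covariates_give_single_leaf_ratio_estimator():
    rng = np.random.default_rng(8)
    n = 30
    X = np.ones((n, 2))
    treat = rng.integers(0, 2, n).astype(np.int64)
    zc = treat - 0.5
    yc = rng.normal(size=n)
    w = rng.uniform(0.5, 2.0, n)
    s_idx, e_idx = np.arange(0, n, 2), np.arange(1, n, 2)
    tree = grow_causal_tree(X, yc, zc, w, treat, s_idx, e_idx,
                            params=ForestParams(min_node_size=1), seed=1)
    assert tree.n_nodes == 1
    expect = (np.sum(w[e_idx] * yc[e_idx] * zc[e_idx])
              / np.sum(w[e_idx] * zc[e_idx] ** 2))
    np.testing.assert_allclose(tree.value[0], expect, rtol=1e-12)


def test_first_split_matches_brute_force_oracle():
    out = studies.split_oracle_study(n_instances=60, seed=123)
    assert out["agreement"] == 1.0


def test_honesty_estimation_half_outcome_never_moves_splits():
    rng = np.random.default_rng(9)
    n = 60
    X = rng.normal(size=(n, 3))
    treat = rng.integers(0, 2, n).astype(np.int64)
    zc = treat - 0.5
    yc = rng.normal(size=n)
    w = np.ones(n)
    perm = rng.permutation(n)
    s_idx, e_idx = perm[:30], perm[30:]
    params = ForestParams(min_node_size=2, mtry=3)
    t1 = grow_causal_tree(X, yc, zc, w, treat, s_idx, e_idx, params=params, seed=4)
    yc2 = yc.copy()
    yc2[e_idx[0]] += 100.0  # violently perturb one estimation-half outcome
    t2 = grow_causal_tree(X, yc2, zc, w, treat, s_idx, e_idx, params=params, seed=4)
    assert t1.structure() == t2.structure()
    # ... while perturbing a split-half outcome may (and here does) matter
    yc3 = yc.copy()
    yc3[s_idx[0]] += 100.0
    t3 = grow_causal_tree(X, yc3, zc, w, treat, s_idx, e_idx, params=params, seed=4)
    assert t1.structure() != t3.structure()


def test_split_and_estimation_halves_disjoint_validation():
    X = np.zeros((4, 1))
    with pytest.raises(ValueError, match="disjoint"):
        grow_causal_tree(X, np.zeros(4), np.zeros(4), np.ones(4),
                         np.array([0, 1, 0, 1]), [0, 1], [1, 2])


# ---------------------------------------------------------------------------
# causal forests
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def fitted_cf():
    from hetforest.datagen import CovariateDef, DGPConfig, EffectDef, OutcomeDef
    covs = [CovariateDef(f"x{i}", p=0.5) for i in range(3)]
    out = OutcomeDef("y", "gaussian", intercept=0.0, noise_scale=1.0,
                     effect=EffectDef("step", on="x0", value_if=3.0, value_else=1.0))
    cfg = DGPConfig(n_households=3200, covariates=covs, outcomes=[out],
                    control_crossover=0.0)
    sample, truth = generate_sample(cfg, 17)
    res = CausalForest(sample, "y", params=ForestParams(n_trees=150, seed=5)).fit()
    return cfg, sample, truth, res


def test_forest_recovers_two_group_effects(fitted_cf):
    _, sample, truth, res = fitted_cf
    tau = res.cate_oob
    x0 = sample.df.cov_x0.to_numpy()[res.kept_idx]
    k = np.isfinite(tau)
    assert abs(tau[k & (x0 == 1)].mean() - 3.0) < 0.3
    assert abs(tau[k & (x0 == 0)].mean() - 1.0) < 0.3


def test_forest_seed_determinism(fitted_cf):
    cfg, sample, _, res = fitted_cf
    res2 = CausalForest(sample, "y", params=ForestParams(n_trees=150, seed=5)).fit()
    np.testing.assert_array_equal(res.cate_oob, res2.cate_oob)
    np.testing.assert_array_equal(res.variable_importance(),
                                  res2.variable_importance())


def test_household_cluster_subsampling_all_in_or_out(fitted_cf):
    _, sample, _, res = fitted_cf
    ff = res.forest
    hh = ff.hh_codes
    for b in (0, 1, 2):
        tree = ff.trees[b]
        used_households = set(hh[tree.split_rows]) | set(hh[tree.est_rows])
        inbag_households = set(np.flatnonzero(ff.inbag[b]))
        assert used_households <= inbag_households
        # every in-bag household contributes all of its members
        rows_used = set(tree.split_rows) | set(tree.est_rows)
        for h in used_households:
            assert set(np.flatnonzero(hh == h)) <= rows_used
        # split and estimation households are disjoint
        assert not (set(hh[tree.split_rows]) & set(hh[tree.est_rows]))


def test_alpha_weights_normalized_and_reproduce_prediction(fitted_cf):
    _, sample, _, res = fitted_cf
    x = sample.X[3]
    alpha = res.alpha_weights(x)
    assert (alpha >= 0).all()
    assert abs(alpha.sum() - 1.0) < 1e-8
    # independent evaluation of the weighted residual-on-residual ratio
    ff = res.forest
    num = np.sum(alpha * ff.w * ff.y * ff.zc)
    den = np.sum(alpha * ff.w * ff.zc * ff.dc)
    pred = res.predict(x[None, :]).tau_hat[0]
    np.testing.assert_allclose(pred, num / den, rtol=1e-9)


def test_single_unsplit_tree_predicts_root_ratio_everywhere():
    from hetforest.datagen import CovariateDef, DGPConfig, EffectDef, OutcomeDef
    covs = [CovariateDef("x0", p=1.0)]  # constant covariate: no admissible split
    out = OutcomeDef("y", "gaussian", effect=EffectDef("constant", value=1.0))
    cfg = DGPConfig(n_households=60, covariates=covs, outcomes=[out],
                    control_crossover=0.0)
    sample, _ = generate_sample(cfg, 23)
    res = CausalForest(sample, "y", params=ForestParams(n_trees=1, seed=6)).fit()
    tree = res.forest.trees[0]
    assert tree.n_nodes == 1
    ff = res.forest
    e = tree.est_rows
    root = (np.sum(ff.w[e] * ff.y[e] * ff.zc[e])
            / np.sum(ff.w[e] * ff.zc[e] * ff.dc[e]))
    preds = res.predict(np.array([[0.0], [1.0]])).tau_hat
    np.testing.assert_allclose(preds, root, rtol=1e-12)


def test_variable_importance_contracts(fitted_cf):
    _, _, _, res = fitted_cf
    imp = res.variable_importance()
    assert (imp >= 0).all()
    assert abs(imp.sum() - 1.0) < 1e-12
    assert imp.argmax() == 0  # the heterogeneity driver


def test_importance_degenerate_single_feature_forest():
    rng = np.random.default_rng(11)
    n = 200
    X = np.column_stack([rng.integers(0, 2, n).astype(float), np.zeros(n)])
    treat = rng.integers(0, 2, n).astype(np.int64)
    zc = treat - 0.5
    yc = np.where(X[:, 0] == 1, 2.0, -2.0) * zc
    from hetforest.forests import _fit_forest
    ff = _fit_forest(1, X, yc, zc, zc, np.ones(n), treat,
                     np.arange(n, dtype=np.int64),
                     ForestParams(n_trees=10, min_node_size=1, mtry=2), seed=3)
    imp = variable_importance(ff)
    assert imp[0] == 1.0 and imp[1] == 0.0


def test_instrumental_forest_equals_causal_under_perfect_compliance():
    from hetforest.datagen import CovariateDef, DGPConfig, EffectDef, OutcomeDef
    covs = [CovariateDef(f"x{i}", p=0.5) for i in range(3)]
    out = OutcomeDef("y", "gaussian", noise_scale=1.0,
                     effect=EffectDef("step", on="x0", value_if=2.0, value_else=0.0))
    cfg = DGPConfig(n_households=300, covariates=covs, outcomes=[out],
                    apply_coefs={"intercept": 50.0}, approve_coefs={"intercept": 50.0},
                    control_crossover=0.0)
    sample, _ = generate_sample(cfg, 29)
    assert np.array_equal(sample.D, sample.Z)  # perfect compliance world
    params = ForestParams(n_trees=40, seed=12)
    cf = CausalForest(sample, "y", params=params).fit(seed=99)
    ivf = InstrumentalForest(sample, "y", params=params).fit(seed=99)
    np.testing.assert_allclose(ivf.cate_oob, cf.cate_oob, rtol=0, atol=1e-9)
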