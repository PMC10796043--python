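"""Simulation validation studies for the estimation machinery.

Each function sets up a synthetic world with known truth, runs the package
end to end, and reports operating characteristics: split-search agreement
with a brute-force oracle, ATE bias and CI coverage, double robustness
under deliberate nuisance misspecification, LATE recovery under one-sided
noncompliance, and the type-I error of the heterogeneity calibration test.
These back the package's acceptance checks and are reusable for benchmark
runs at other problem sizes.
"""

from __future__ import annotations

import numpy as np

from .datagen import (CovariateDef, DGPConfig, EffectDef, OutcomeDef,
                      generate_sample)
from .estimation import aipw_scores, average_effect, late_effect
from .forests import CausalForest, ForestParams, grow_causal_tree
from .heterogeneity import calibration_test_crossfit

__all__ = [
    "constant_effect_config",
    "two_group_config",
    "noncompliance_config",
    "brute_force_best_split",
    "split_oracle_study",
    "ate_recovery_study",
    "double_robustness_study",
    "late_recovery_study",
    "calibration_type1_study",
    "funnel_rates",
]


# ---------------------------------------------------------------------------
# reference DGP configurations (the study conditions for validation)
# ---------------------------------------------------------------------------

def constant_effect_config(n_households: int = 1500, tau: float = 1.0,
                           noise: float = 1.0, n_covariates: int = 4,
                           weight_sigma: float = 0.3) -> DGPConfig:
    """Household-clustered randomized design with a constant effect."""
    covs = [CovariateDef(f"x{i}", p=0.5) for i in range(n_covariates)]
    out = OutcomeDef("y", "gaussian", intercept=1.0,
                     coefs={"x0": 1.0, "x1": -0.5}, noise_scale=noise,
                     effect=EffectDef("constant", value=tau))
    return DGPConfig(n_households=n_households, covariates=covs, outcomes=[out],
                     control_crossover=0.0, weight_sigma=weight_sigma)


def two_group_config(n_households: int = 1500, tau_if: float = 3.0,
                     tau_else: float = 1.0, on: str = "x0",
                     noise: float = 1.0) -> DGPConfig:
    """Step-function heterogeneity on one binary covariate."""
    covs = [CovariateDef(f"x{i}", p=0.5) for i in range(4)]
    out = OutcomeDef("y", "gaussian", intercept=0.0, noise_scale=noise,
                     effect=EffectDef("step", on=on, value_if=tau_if,
                                      value_else=tau_else))
    return DGPConfig(n_households=n_households, covariates=covs, outcomes=[out],
                     control_crossover=0.0)


def noncompliance_config(n_households: int = 3200, compliance: float = 0.5,
                         complier_effect: float = 2.0) -> DGPConfig:
    """One-sided noncompliance: effect flows through enrollment D only."""
    covs = [CovariateDef(f"x{i}", p=0.5) for i in range(4)]
    out = OutcomeDef("y", "gaussian", intercept=0.0, coefs={"x0": 0.5},
                     noise_scale=1.0,
                     effect=EffectDef("constant", value=complier_effect))
    logit_c = float(np.log(compliance / (1 - compliance)))
    return DGPConfig(n_households=n_households, covariates=covs, outcomes=[out],
                     apply_coefs={"intercept": logit_c},
                     approve_coefs={"intercept": 50.0},  # every applicant approved
                     control_crossover=0.0, effect_channel="treatment")


# ---------------------------------------------------------------------------
# split-search oracle
# ---------------------------------------------------------------------------

def brute_force_best_split(X, yc, zc, w, treat, split_idx, est_idx,
                           min_node_size: int = 1, alpha: float = 0.05,
                           penalty: float = 0.0):
    """Exhaustive search over every (covariate, threshold) candidate.

    Independent re-implementation of the heterogeneity splitting criterion
    using vectorized numpy over explicit candidate enumeration. Returns
    (feature, threshold) or None when no candidate beats leaving the node
    unsplit. Tie-break: lowest covariate index, then lowest threshold.
    """
    X = np.asarray(X, float)
    yc = np.asarray(yc, float)
    zc = np.asarray(zc, float)
    w = np.asarray(w, float)
    treat = np.asarray(treat, int)
    s = np.asarray(split_idx, int)
    e = np.asarray(est_idx, int)
    n_tr, n_est = len(s), len(e)
    coef = 1.0 / n_tr + 1.0 / n_est

    def node_contrib(rows):
        """Per-leaf term of the criterion on split-half rows; None if degenerate."""
        t = rows[treat[rows] == 1]
        c = rows[treat[rows] == 0]
        if len(t) == 0 or len(c) == 0:
            return None
        den = np.sum(w[rows] * zc[rows] * zc[rows])
        if abs(den) <= 1e-12:
            return None
        tau = np.sum(w[rows] * yc[rows] * zc[rows]) / den
        p = len(t) / len(rows)

        def wvar(rr):
            ww = w[rr]
            mu = np.sum(ww * yc[rr]) / ww.sum()
            return np.sum(ww * (yc[rr] - mu) ** 2) / ww.sum()

        return (len(rows) / n_tr) * tau ** 2 - coef * (wvar(t) / p + wvar(c) / (1 - p))

    best = None
    best_crit = -np.inf  # argmax among valid candidates; no parent gate
    alpha_n = max(1, int(np.ceil(alpha * n_tr)))
    p_features = X.shape[1]
    for f in range(p_features):
        vals = np.unique(X[s, f])
        thresholds = 0.5 * (vals[:-1] + vals[1:])
        for thr in thresholds:
            left = s[X[s, f] <= thr]
            right = s[X[s, f] > thr]
            if len(left) < alpha_n or len(right) < alpha_n:
                continue
            eL = e[X[e, f] <= thr]
            eR = e[X[e, f] > thr]
            for side in (eL, eR):
                nt = int((treat[side] == 1).sum())
                nc = len(side) - nt
                if nt < min_node_size or nc < min_node_size:
                    break
            else:
                cl = node_contrib(left)
                cr = node_contrib(right)
                if cl is None or cr is None:
                    continue
                crit = cl + cr - penalty * (1.0 / len(left) + 1.0 / len(right))
                if crit > best_crit:
                    best_crit = crit
                    best = (f, float(thr))
    return best


def split_oracle_study(n_instances: int = 200, seed: int = 0) -> dict:
    """Fraction of random small instances where the grown first split equals
    the exhaustive-search maximizer."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(5,)))
    agree = 0
    for _ in range(n_instances):
        n = int(rng.integers(16, 31))
        p = int(rng.integers(1, 4))
        X = rng.normal(size=(n, p))
        treat = rng.integers(0, 2, size=n)
        if treat.sum() in (0, n):
            treat[0] = 1 - treat[0]
        zc = treat - 0.5
        yc = rng.normal(size=n) + treat * rng.normal(scale=0.5, size=n)
        w = rng.uniform(0.5, 1.5, size=n)
        perm = rng.permutation(n)
        s_idx, e_idx = perm[: n // 2], perm[n // 2:]
        params = ForestParams(n_trees=1, min_node_size=1, alpha_imbalance=0.05,
                              mtry=p, max_depth=1)
        tree = grow_causal_tree(X, yc, zc, w, treat, s_idx, e_idx,
                                params=params, seed=int(rng.integers(2 ** 31)))
        grown = tree.root_split()
        oracle = brute_force_best_split(X, yc, zc, w, treat, s_idx, e_idx,
                                        min_node_size=1, alpha=0.05)
        if grown is None and oracle is None:
            agree += 1
        elif grown is not None and oracle is not None:
            if grown[0] == oracle[0] and abs(grown[1] - oracle[1]) < 1e-9:
                agree += 1
    return {"agreement": agree / n_instances, "n_instances": n_instances}


# ---------------------------------------------------------------------------
# replicate studies
# ---------------------------------------------------------------------------

def ate_recovery_study(n_reps: int = 200, n_households: int = 1500,
                       n_trees: int = 150, tau: float = 1.0, seed: int = 0) -> dict:
    """Bias and 95% CI coverage of the AIPW ATE under a constant effect."""
    cfg = constant_effect_config(n_households=n_households, tau=tau)
    estimates, covered, ns = [], 0, []
    for rep in range(n_reps):
        sample, _ = generate_sample(cfg, seed * 100003 + rep)
        res = CausalForest(sample, "y",
                           params=ForestParams(n_trees=n_trees, seed=seed + rep)).fit()
        est = res.ate()
        estimates.append(est.estimate)
        covered += int(est.ci_low <= tau <= est.ci_high)
        ns.append(sample.n)
    estimates = np.asarray(estimates)
    return {
        "bias": float(estimates.mean() - tau),
        "mc_se": float(estimates.std(ddof=1) / np.sqrt(n_reps)),
        "coverage": covered / n_reps,
        "n_reps": n_reps,
        "mean_n": float(np.mean(ns)),
    }


def double_robustness_study(n_reps: int = 200, n_households: int = 1600,
                            tau: float = 1.0, seed: int = 0) -> dict:
    """ATE bias with one nuisance deliberately misspecified.

    Arm "wrong_outcome_model": the propensity is the true assignment
    probability but the outcome mean is a wrong constant (and the CATE
    plug-in zero). Arm "wrong_propensity": outcome mean and CATE are exact
    but the propensity is a wrong constant inside (0.2, 0.8). Either way
    the doubly robust score should stay unbiased.
    """
    cfg = constant_effect_config(n_households=n_households, tau=tau,
                                 weight_sigma=0.0)
    est_a, est_b = [], []
    e_wrong = 0.3
    for rep in range(n_reps):
        sample, truth = generate_sample(cfg, seed * 999983 + rep)
        y, z, w, hh = sample.outcome("y"), sample.Z, sample.weight, sample.household_id
        n = sample.n
        X = sample.df
        mu = 1.0 + 1.0 * X["cov_x0"].to_numpy() - 0.5 * X["cov_x1"].to_numpy()
        tau_true = truth.tau["y"]
        # (a) true propensity, wrong outcome model
        sa = aipw_scores(y, z, m_hat=np.full(n, 5.0), e_hat=np.full(n, cfg.p_select),
                         cate_oob=np.zeros(n), weights=w, households=hh)
        est_a.append(average_effect(sa).estimate)
        # (b) exact outcome model and CATE, misspecified propensity
        m_b = mu + e_wrong * tau_true  # marginal mean consistent with the wrong e
        sb = aipw_scores(y, z, m_hat=m_b, e_hat=np.full(n, e_wrong),
                         cate_oob=tau_true, weights=w, households=hh)
        est_b.append(average_effect(sb).estimate)
    est_a, est_b = np.asarray(est_a), np.asarray(est_b)
    return {
        "bias_wrong_outcome_model": float(est_a.mean() - tau),
        "mc_se_wrong_outcome_model": float(est_a.std(ddof=1) / np.sqrt(n_reps)),
        "bias_wrong_propensity": float(est_b.mean() - tau),
        "mc_se_wrong_propensity": float(est_b.std(ddof=1) / np.sqrt(n_reps)),
        "n_reps": n_reps,
    }


def late_recovery_study(n_households: int = 3200, n_trees: int = 200,
                        compliance: float = 0.5, complier_effect: float = 2.0,
                        seed: int = 0) -> dict:
    """ITT vs complier effect under one-sided noncompliance."""
    cfg = noncompliance_config(n_households=n_households, compliance=compliance,
                               complier_effect=complier_effect)
    sample, _ = generate_sample(cfg, seed)
    params = ForestParams(n_trees=n_trees, seed=seed)
    res_y = CausalForest(sample, "y", params=params).fit(seed=seed * 7 + 1)
    res_d = CausalForest(sample, "D", params=params).fit(seed=seed * 7 + 2)
    itt = res_y.ate()
    first = res_d.ate()
    late = late_effect(res_y.aipw_scores(), res_d.aipw_scores(), label="late")
    return {
        "itt": itt.estimate, "itt_se": itt.se,
        "first_stage": first.estimate,
        "late": late.estimate, "late_se": late.se,
        "n": sample.n,
    }


def calibration_type1_study(n_reps: int = 200, n_households: int = 800,
                            n_trees: int = 100, seed: int = 0) -> dict:
    """Rejection rate of the one-sided heterogeneity test under homogeneity.

    Uses the cross-fitted calibration test, whose null distribution is close
    to standard normal at these sample sizes (the within-forest variant is
    conservative; see :func:`hetforest.heterogeneity.calibration_test`).
    """
    cfg = constant_effect_config(n_households=n_households, tau=1.0,
                                 weight_sigma=0.0)
    rejects, estimable = 0, 0
    for rep in range(n_reps):
        sample, _ = generate_sample(cfg, seed * 424243 + rep)
        cal = calibration_test_crossfit(
            sample, "y", params=ForestParams(n_trees=n_trees, seed=seed + rep),
            seed=seed + rep)
        if cal.beta_estimable:
            estimable += 1
            rejects += int(cal.p_beta < 0.05)
    return {
        "rejection_rate": rejects / max(estimable, 1),
        "n_estimable": estimable,
        "n_reps": n_reps,
    }


def funnel_rates(n_selected: int, n_applied: int, n_approved: int) -> dict:
    """Stage percentages of an application/approval funnel from raw counts."""
    if not (0 <= n_approved <= n_applied <= n_selected) or n_selected == 0:
        raise ValueError("counts must satisfy 0 <= approved <= applied <= selected")
    return {
        "applied_pct": 100.0 * n_applied / n_selected,
        "not_applied_pct": 100.0 * (n_selected - n_applied) / n_selected,
        "approved_pct": 100.0 * n_approved / n_applied if n_applied else float("nan"),
        "rejected_pct": 100.0 * (n_applied - n_approved) / n_applied if n_applied else float("nan"),
    }
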