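"""Orchestration of the full heterogeneity analysis.

Mirrors the study workflow: random-search hyperparameter tuning against the
out-of-bag R-loss, a two-stage fit that refits on the covariates whose
depth-weighted importance exceeds a fraction of the mean importance,
per-outcome intent-to-treat (and optionally instrumental) forests with
AIPW ATE/GATE tables over the prespecified subgroups, the omnibus
calibration test, covariate balance diagnostics, and the three-stage
application -> approval -> uptake decomposition.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datagen import ObservationalSample, make_subgroups
from .estimation import (average_effect, balance_table, group_average_effect,
                         late_effect)
from .forests import (CausalForest, CausalForestResults, ForestParams,
                      InstrumentalForest, variable_importance)
from .heterogeneity import calibration_test

logger = logging.getLogger(__name__)

__all__ = [
    "TuningBudget",
    "AnalysisConfig",
    "StageResults",
    "AnalysisReport",
    "tune_hyperparameters",
    "retain_covariates",
    "two_stage_fit",
    "uptake_decomposition",
    "run_analysis",
]


@dataclass
class TuningBudget:
    """Random-search budget for hyperparameter tuning.

    The full-scale configuration of the motivating study draws 5,000
    candidate parameter vectors and evaluates them with >= 500-tree forests
    (1,000 forests for the tuning model); the desk-scale default is a direct
    random search with 50 draws and 200-tree forests.
    """

    n_candidate_draws: int = 50
    trees_per_tuning_forest: int = 200
    n_tuning_forests: int = 50

    @classmethod
    def paper_scale(cls) -> "TuningBudget":
        return cls(n_candidate_draws=5000, trees_per_tuning_forest=500,
                   n_tuning_forests=1000)


@dataclass
class AnalysisConfig:
    """Configuration for a full analysis run."""

    outcomes: list[str] | None = None        # None -> every outcome in the sample
    treatment: str = "Z"
    params: ForestParams = field(default_factory=ForestParams)
    tuning: TuningBudget | None = None       # None -> skip tuning, use params
    retention_threshold: float = 0.20        # fraction of mean importance
    subgroups: list[str] | None = None       # None -> all prespecified masks
    iv: bool = False
    weighted_balance: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.retention_threshold < 1.0):
            raise ValueError("retention_threshold must be in (0, 1)")
        self.params.validate()


# ---------------------------------------------------------------------------
# tuning
# ---------------------------------------------------------------------------

_TUNE_RANGES = {
    "sample_fraction": (0.20, 0.50),
    "honesty_fraction": (0.40, 0.60),
    "alpha_imbalance": (0.01, 0.25),
    "imbalance_penalty": (0.0, 2.0),
}


def _draw_candidate(rng: np.random.Generator, p: int, base: ForestParams) -> ForestParams:
    lo, hi = _TUNE_RANGES["sample_fraction"]
    sf = rng.uniform(lo, hi)
    lo, hi = _TUNE_RANGES["honesty_fraction"]
    hf = rng.uniform(lo, hi)
    lo, hi = _TUNE_RANGES["alpha_imbalance"]
    al = rng.uniform(lo, hi)
    lo, hi = _TUNE_RANGES["imbalance_penalty"]
    pen = rng.uniform(lo, hi) if rng.random() < 0.5 else 0.0
    return replace(base, sample_fraction=sf, honesty_fraction=hf,
                   mtry=int(rng.integers(1, p + 1)),
                   min_node_size=int(np.exp(rng.uniform(np.log(5), np.log(50)))),
                   alpha_imbalance=al, imbalance_penalty=pen)


def _r_loss(results: CausalForestResults) -> float:
    """Weighted out-of-bag R-loss 1/2 [Yc - tau(x)(Zc)]^2."""
    tau = results.cate_oob
    keep = np.isfinite(tau)
    yc = results.y - results.m_hat
    zc = results.z - results.e_hat
    w = results.w
    res = yc[keep] - tau[keep] * zc[keep]
    return float(0.5 * np.sum(w[keep] * res ** 2) / np.sum(w[keep]))


def tune_hyperparameters(sample: ObservationalSample, outcome: str,
                         budget: TuningBudget | None, seed: int = 0,
                         treatment: str = "Z",
                         base_params: ForestParams | None = None
                         ) -> tuple[ForestParams, pd.DataFrame]:
    """Random-search tuning scored by the out-of-bag R-loss.

    The default parameter vector is always candidate 0, so the selected
    parameters never degrade the tuning objective relative to the defaults.
    A zero/None budget returns the defaults unchanged. Nuisance fits are
    shared across candidates (only the causal trees are regrown).
    """
    base = base_params or ForestParams()
    if budget is None or budget.n_candidate_draws <= 0:
        return base, pd.DataFrame()
    p = sample.X.shape[1]
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(11,)))
    small = replace(base, n_trees=budget.trees_per_tuning_forest)
    model = CausalForest(sample, outcome, treatment=treatment, params=small)
    nuisance = model._fit_nuisance(seed)
    candidates = [small] + [_draw_candidate(rng, p, small)
                            for _ in range(budget.n_candidate_draws)]
    rows = []
    best_loss, best = np.inf, small
    for i, cand in enumerate(candidates):
        cand_model = CausalForest(sample, outcome, treatment=treatment, params=cand)
        res = cand_model.fit(seed=seed, nuisance=nuisance)
        loss = _r_loss(res)
        rows.append({"candidate": i, "r_loss": loss, **{k: getattr(cand, k) for k in (
            "sample_fraction", "honesty_fraction", "mtry", "min_node_size",
            "alpha_imbalance", "imbalance_penalty")}})
        if loss < best_loss:
            best_loss, best = loss, cand
    tuned = replace(best, n_trees=base.n_trees)
    return tuned, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# two-stage fit with covariate selection
# ---------------------------------------------------------------------------

def retain_covariates(importances: np.ndarray, names: list[str],
                      threshold: float = 0.20) -> list[str]:
    """Names whose importance exceeds ``threshold`` times the mean importance."""
    imp = np.asarray(importances, float)
    if len(imp) != len(names):
        raise ValueError("importances and names must align")
    cut = threshold * imp.mean()
    kept = [n for n, v in zip(names, imp) if v > cut]
    if not kept:
        raise RuntimeError("no covariates retained; threshold logic violated")
    return kept


def two_stage_fit(sample: ObservationalSample, outcome: str,
                  config: AnalysisConfig, params: ForestParams | None = None,
                  seed: int | None = None, treatment: str | None = None
                  ) -> tuple[CausalForestResults, list[str]]:
    """Fit on all covariates, keep the important ones, refit on those."""
    params = params or config.params
    seed = config.seed if seed is None else seed
    treatment = treatment or config.treatment
    stage1 = CausalForest(sample, outcome, treatment=treatment, params=params).fit(seed=seed)
    imp = stage1.variable_importance()
    retained = retain_covariates(imp, sample.covariate_names, config.retention_threshold)
    if len(retained) == len(sample.covariate_names):
        stage2 = CausalForest(sample, outcome, treatment=treatment,
                              params=params).fit(seed=seed + 1)
        return stage2, retained
    sub = sample.select_covariates(retained)
    stage2 = CausalForest(sub, outcome, treatment=treatment,
                          params=params).fit(seed=seed + 1)
    return stage2, retained


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def _gate_table(results: CausalForestResults, masks: dict[str, np.ndarray],
                outcome: str, analysis: str) -> pd.DataFrame:
    scores = results.aipw_scores()
    rows = []
    for name, mask in masks.items():
        est = group_average_effect(scores, scores.mask_rows(np.asarray(mask, bool)),
                                   label=name)
        rows.append({"outcome": outcome, "analysis": analysis, "subgroup": name,
                     "estimate": est.estimate, "se": est.se,
                     "ci_low": est.ci_low, "ci_high": est.ci_high,
                     "n_persons": est.n_persons, "n_households": est.n_households,
                     "p_value": est.p_value})
    return pd.DataFrame(rows)


@dataclass
class StageResults:
    """The uptake-funnel decomposition: one forest per stage plus gap summaries."""

    results: dict[str, CausalForestResults]
    gate_tables: pd.DataFrame
    stage_gaps: pd.DataFrame

    def summary(self) -> str:
        lines = ["Uptake decomposition (intent-to-treat per stage):"]
        for stage, res in self.results.items():
            est = res.ate()
            lines.append(f"  {stage:>9}: {est.estimate:8.4f} "
                         f"({est.ci_low:.4f}, {est.ci_high:.4f})")
        for _, row in self.stage_gaps.iterrows():
            lines.append(f"  gap {row.transition}: {row.gap:8.4f}")
        return "\n".join(lines)


def uptake_decomposition(sample: ObservationalSample, config: AnalysisConfig,
                         masks: dict[str, np.ndarray] | None = None) -> StageResults:
    """Three intent-to-treat forests: applied, approved, enrolled (uptake)."""
    sample.validate()
    config.validate()
    if masks is None:
        masks = make_subgroups(sample)
    stages = {"applied": "applied", "approved": "approved", "uptake": "D"}
    results: dict[str, CausalForestResults] = {}
    tables = []
    for k, (stage, col) in enumerate(stages.items()):
        t0 = time.perf_counter()
        res = CausalForest(sample, col, treatment="Z", params=config.params).fit(
            seed=config.seed * 31 + k)
        results[stage] = res
        tables.append(_gate_table(res, masks, stage, "itt"))
        logger.info("stage %s fitted in %.1fs", stage, time.perf_counter() - t0)
    ates = {s: results[s].ate().estimate for s in stages}
    gaps = pd.DataFrame([
        {"transition": "application_to_approval", "gap": ates["applied"] - ates["approved"]},
        {"transition": "approval_to_uptake", "gap": ates["approved"] - ates["uptake"]},
    ])
    return StageResults(results=results, gate_tables=pd.concat(tables, ignore_index=True),
                        stage_gaps=gaps)


@dataclass
class AnalysisReport:
    """Tidy result bundle: the machine-readable analogue of the effect tables."""

    ate_gate: pd.DataFrame
    balance: pd.DataFrame
    diagnostics: pd.DataFrame
    uptake_stages: pd.DataFrame | None
    manifest: dict
    forests: dict[str, CausalForestResults] = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["Analysis report", "==============="]
        overall = self.ate_gate[(self.ate_gate.subgroup == "overall")
                                & (self.ate_gate.analysis == "itt")]
        for _, r in overall.iterrows():
            lines.append(f"  {r.outcome:>20}: ATE {r.estimate:9.4f} "
                         f"({r.ci_low:.4f}, {r.ci_high:.4f})")
        for _, r in self.diagnostics.iterrows():
            lines.append(f"  calibration[{r.outcome}]: alpha={r.alpha:.3f} "
                         f"beta={r.beta if np.isfinite(r.beta) else float('nan'):.3f} "
                         f"p[beta>0]={r.p_beta:.3f}")
        return "\n".join(lines)


def run_analysis(sample: ObservationalSample, config: AnalysisConfig,
                 include_uptake: bool = True) -> AnalysisReport:
    """The full per-outcome analysis; deterministic given config.seed."""
    sample.validate()
    config.validate()
    outcomes = config.outcomes or sample.outcome_names
    masks = make_subgroups(sample)
    if config.subgroups is not None:
        masks = {k: masks[k] for k in ["overall"] + list(config.subgroups)}
    gate_rows = []
    diag_rows = []
    forests: dict[str, CausalForestResults] = {}
    manifest = {"seed": config.seed, "outcomes": list(outcomes),
                "n_persons": sample.n,
                "n_households": int(len(np.unique(sample.household_id))),
                "params": {k: getattr(config.params, k) for k in (
                    "n_trees", "sample_fraction", "honesty_fraction", "mtry",
                    "min_node_size", "alpha_imbalance", "imbalance_penalty")},
                "retained_covariates": {}, "tuned_params": {}, "drop_counts": {}}

    scores_d = None
    if config.iv:
        cf_d = CausalForest(sample, "D", treatment=config.treatment,
                            params=config.params).fit(seed=config.seed * 31 + 29)
        scores_d = cf_d.aipw_scores()

    for j, outcome in enumerate(outcomes):
        t0 = time.perf_counter()
        seed_j = config.seed * 101 + 7 * j
        params_j = config.params
        if config.tuning is not None and config.tuning.n_candidate_draws > 0:
            params_j, _ = tune_hyperparameters(sample, outcome, config.tuning,
                                               seed=seed_j, treatment=config.treatment,
                                               base_params=config.params)
            manifest["tuned_params"][outcome] = {
                k: getattr(params_j, k) for k in (
                    "sample_fraction", "honesty_fraction", "mtry",
                    "min_node_size", "alpha_imbalance", "imbalance_penalty")}
        res, retained = two_stage_fit(sample, outcome, config, params=params_j,
                                      seed=seed_j)
        forests[outcome] = res
        manifest["retained_covariates"][outcome] = retained
        manifest["drop_counts"][outcome] = int(sample.n - len(res.kept_idx))
        gate_rows.append(_gate_table(res, masks, outcome, "itt"))
        cal = calibration_test(res)
        diag_rows.append({"outcome": outcome, "alpha": cal.alpha, "beta": cal.beta,
                          "se_alpha": cal.se_alpha, "se_beta": cal.se_beta,
                          "p_beta": cal.p_beta, "beta_estimable": cal.beta_estimable})
        if config.iv and scores_d is not None:
            # LATE analogue per subgroup: ratio of clustered score means
            from .estimation import align_scores
            sy, sd = align_scores(res.aipw_scores(), scores_d)
            for name, mask in masks.items():
                msk = sy.mask_rows(np.asarray(mask, bool))
                if not msk.any():
                    continue
                est = late_effect(sy.restrict(msk), sd.restrict(msk), label=name)
                gate_rows.append(pd.DataFrame([{
                    "outcome": outcome, "analysis": "iv", "subgroup": name,
                    "estimate": est.estimate, "se": est.se, "ci_low": est.ci_low,
                    "ci_high": est.ci_high, "n_persons": est.n_persons,
                    "n_households": est.n_households, "p_value": est.p_value}]))
        logger.info("outcome %s analysed in %.1fs", outcome, time.perf_counter() - t0)

    table = pd.concat(gate_rows, ignore_index=True)
    # documentation-only multiplicity flag over the subgroup x outcome tests
    itt_sub = (table.analysis == "itt") & (table.subgroup != "overall")
    n_tests = int(itt_sub.sum())
    table["significant_bonferroni"] = False
    if n_tests:
        table.loc[itt_sub, "significant_bonferroni"] = (
            table.loc[itt_sub, "p_value"] < 0.05 / n_tests)

    # partition identity check: sex GATEs must recombine to the ATE
    for outcome in outcomes if "males" in masks else []:
        res = forests[outcome]
        scores = res.aipw_scores()
        males = scores.mask_rows(np.asarray(masks["males"], bool))
        ga = group_average_effect(scores, males, "m")
        gb = group_average_effect(scores, ~males, "f")
        wa = scores.weights[males].sum()
        wb = scores.weights[~males].sum()
        recombined = (ga.estimate * wa + gb.estimate * wb) / (wa + wb)
        dev = abs(recombined - average_effect(scores).estimate)
        if dev > 1e-8:
            raise AssertionError(f"partition identity violated for {outcome}: {dev:g}")

    balance = pd.concat([balance_table(sample, "Z", config.weighted_balance),
                         balance_table(sample, "D", config.weighted_balance)],
                        ignore_index=True)
    uptake_table = None
    if include_uptake and "applied" in sample.df.columns:
        uptake = uptake_decomposition(sample, config, masks=masks)
        uptake_table = uptake.gate_tables
        manifest["stage_gaps"] = {r.transition: float(r.gap)
                                  for r in uptake.stage_gaps.itertuples()}

    return AnalysisReport(
        ate_gate=table,
        balance=balance,
        diagnostics=pd.DataFrame(diag_rows),
        uptake_stages=uptake_table,
        manifest=manifest,
        forests=forests,
    )
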