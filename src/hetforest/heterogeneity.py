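"""Diagnostics for whether estimated effect heterogeneity is real.

Three tools, all survey-weighted and household-clustered:

* the omnibus *calibration test* (best-linear-predictor construction):
  regress the centered outcome on the two constructed regressors
  (Z - e)(mean OOB CATE) and (Z - e)(OOB CATE - mean); a mean-prediction
  coefficient alpha near 1 says the forest's average is well calibrated, a
  differential coefficient beta > 0 says the forest's *ranking* of effects
  carries signal (one-sided test);
* the *targeting operator characteristic* (TOC): average AIPW score among
  the top-q fraction ranked by a priority rule, minus the overall average;
* *RATE*, the area under the TOC, estimated with honest half-sample
  splitting (fit the ranking on one household half, evaluate on the other).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .datagen import ObservationalSample
from .estimation import AIPWScoreSet
from .forests import CausalForest, CausalForestResults, ForestParams

__all__ = ["CalibrationResult", "TOCCurve", "calibration_test",
           "calibration_test_crossfit", "toc_curve", "rate_with_se"]


@dataclass
class CalibrationResult:
    alpha: float
    beta: float
    se_alpha: float
    se_beta: float
    p_beta: float
    beta_estimable: bool = True

    def __str__(self) -> str:
        if not self.beta_estimable:
            return (f"calibration: alpha={self.alpha:.3f} (SE {self.se_alpha:.3f}); "
                    "beta not estimable (constant CATE predictions)")
        return (f"calibration: alpha={self.alpha:.3f} (SE {self.se_alpha:.3f}), "
                f"beta={self.beta:.3f} (SE {self.se_beta:.3f}), "
                f"one-sided p[beta>0]={self.p_beta:.4f}")


@dataclass
class TOCCurve:
    q_grid: np.ndarray
    toc: np.ndarray
    rate: float
    se_rate: float | None = None

    def __str__(self) -> str:
        se = f" (SE {self.se_rate:.4f})" if self.se_rate is not None else ""
        return f"RATE = {self.rate:.4f}{se} over {len(self.q_grid)} grid points"


def _calibration(yc, zres, tau_oob, w, households) -> CalibrationResult:
    keep = np.isfinite(tau_oob)
    yc, zres, tau, w, hh = (a[keep] for a in (yc, zres, tau_oob, w, households))
    sw = w.sum()
    tau_bar = float(np.sum(w * tau) / sw)
    mean_reg = zres * tau_bar
    diff_reg = zres * (tau - tau_bar)
    var_tau = float(np.sum(w * (tau - tau_bar) ** 2) / sw)
    if var_tau <= 1e-14:
        res = sm.WLS(yc, mean_reg[:, None], weights=w).fit(
            cov_type="cluster", cov_kwds={"groups": hh})
        return CalibrationResult(float(res.params[0]), np.nan,
                                 float(res.bse[0]), np.nan, np.nan,
                                 beta_estimable=False)
    exog = np.column_stack([mean_reg, diff_reg])
    res = sm.WLS(yc, exog, weights=w).fit(cov_type="cluster", cov_kwds={"groups": hh})
    alpha, beta = (float(v) for v in res.params)
    se_a, se_b = (float(v) for v in res.bse)
    p_beta = float(stats.norm.sf(beta / se_b)) if se_b > 0 else np.nan
    return CalibrationResult(alpha, beta, se_a, se_b, p_beta)


def calibration_test(results: CausalForestResults) -> CalibrationResult:
    """Omnibus heterogeneity calibration test on a fitted forest.

    Uses the forest's own out-of-bag CATEs as the differential regressor.
    Note: when true effect heterogeneity is absent and samples are modest,
    this within-forest version is conservative (the OOB CATEs of *other*
    rows embed each row's residual product, tilting the differential
    coefficient negative); :func:`calibration_test_crossfit` removes that
    leakage by ranking with a forest fit on a disjoint household half.
    """
    yc = results.y - results.m_hat
    zres = results.z - results.e_hat
    return _calibration(yc, zres, results.cate_oob, results.w, results.households)


def calibration_test_crossfit(sample: ObservationalSample, outcome: str,
                              params: ForestParams | None = None,
                              seed: int = 0, treatment: str = "Z") -> CalibrationResult:
    """Cross-fitted calibration test with the same regressors.

    Households are split in half; a forest fit on one half supplies the
    CATE predictions for the other, whose own forest supplies the centered
    outcome and assignment residuals. Under a homogeneous-effect null the
    differential coefficient's one-sided test is then close to nominal.
    """
    params = params or ForestParams()
    hh = np.unique(sample.household_id)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(13,)))
    half = set(rng.permutation(hh)[: len(hh) // 2].tolist())
    in_a = np.array([h in half for h in sample.household_id])
    samp_a = sample.subset(in_a)
    samp_b = sample.subset(~in_a)
    fit_a = CausalForest(samp_a, outcome, treatment=treatment, params=params).fit(
        seed=seed * 2 + 1)
    fit_b = CausalForest(samp_b, outcome, treatment=treatment, params=params).fit(
        seed=seed * 2 + 2)
    tau_b = fit_a.predict(samp_b.X).tau_hat[fit_b.kept_idx]
    return _calibration(fit_b.y - fit_b.m_hat, fit_b.z - fit_b.e_hat,
                        tau_b, fit_b.w, fit_b.households)


def toc_curve(scores_eval: AIPWScoreSet, priority, q_grid=None,
              weighting: str = "autoc") -> TOCCurve:
    """TOC curve and its area statistic for one priority ranking.

    The priority and the evaluation scores should come from disjoint halves
    of the data (documented contract). ``weighting`` "autoc" integrates
    TOC(q) dq; "qini" integrates q*TOC(q) dq.
    """
    priority = np.asarray(priority, float)
    if len(priority) != len(scores_eval):
        raise ValueError("priority must align with the evaluation scores")
    if q_grid is None:
        q_grid = np.linspace(0.01, 1.0, 100)
    q_grid = np.asarray(q_grid, float)
    if len(np.unique(priority)) < len(priority):
        warnings.warn("ties in priority broken by stable order", RuntimeWarning)
    order = np.argsort(-priority, kind="stable")
    g = scores_eval.gamma[order].astype(float)
    w = scores_eval.weights[order]
    # tie groups contribute their weighted mean score, so an uninformative
    # (constant) priority yields TOC identically zero rather than an
    # arbitrary-order artifact
    pr = priority[order]
    start = 0
    for i in range(1, len(pr) + 1):
        if i == len(pr) or pr[i] != pr[start]:
            if i - start > 1:
                g[start:i] = np.sum(w[start:i] * g[start:i]) / np.sum(w[start:i])
            start = i
    cw = np.cumsum(w)
    sw = cw[-1]
    overall = float(np.sum(w * g) / sw)
    cwg = np.cumsum(w * g)
    toc = np.empty_like(q_grid)
    for i, q in enumerate(q_grid):
        k = int(np.searchsorted(cw, q * sw, side="left"))
        k = min(k, len(g) - 1)
        toc[i] = cwg[k] / cw[k] - overall
    integrand = toc if weighting == "autoc" else q_grid * toc
    rate = float(np.trapezoid(integrand, q_grid))
    return TOCCurve(q_grid=q_grid, toc=toc, rate=rate)


def rate_with_se(sample: ObservationalSample, outcome: str,
                 params: ForestParams | None = None, n_half_splits: int = 10,
                 seed: int = 0, treatment: str = "Z", q_grid=None,
                 weighting: str = "autoc") -> TOCCurve:
    """Honest RATE: repeated household-level half-sample splits.

    Each split fits a forest on one half to *rank* the other half, fits a
    second forest on the evaluation half for its own OOB AIPW scores, and
    computes the TOC area there. Reports the mean curve/area and the
    empirical SE of the area across splits.
    """
    if n_half_splits < 2:
        raise ValueError("n_half_splits must be >= 2")
    params = params or ForestParams()
    hh = np.unique(sample.household_id)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(77,)))
    rates, curves = [], []
    qg = np.linspace(0.01, 1.0, 100) if q_grid is None else np.asarray(q_grid, float)
    for s in range(n_half_splits):
        perm = rng.permutation(hh)
        half_a = set(perm[: len(hh) // 2].tolist())
        in_a = np.array([h in half_a for h in sample.household_id])
        samp_a = sample.subset(in_a)
        samp_b = sample.subset(~in_a)
        fit_a = CausalForest(samp_a, outcome, treatment=treatment, params=params).fit(
            seed=seed * 1009 + 2 * s)
        fit_b = CausalForest(samp_b, outcome, treatment=treatment, params=params).fit(
            seed=seed * 1009 + 2 * s + 1)
        priority_b = fit_a.predict(samp_b.X).tau_hat
        scores_b = fit_b.aipw_scores()
        keep = np.isfinite(priority_b[fit_b.kept_idx])
        curve = toc_curve(scores_b.restrict(keep),
                          priority_b[fit_b.kept_idx][keep], q_grid=qg,
                          weighting=weighting)
        rates.append(curve.rate)
        curves.append(curve.toc)
    rates = np.asarray(rates)
    se = float(rates.std(ddof=1) / np.sqrt(n_half_splits))
    return TOCCurve(q_grid=qg, toc=np.mean(curves, axis=0),
                    rate=float(rates.mean()), se_rate=se)
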