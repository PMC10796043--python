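"""AIPW effect estimation with survey weights and household clustering.

The per-person doubly robust score for a binary randomized assignment Z is

    gamma_i = m(X_i,1) - m(X_i,0)
              + (Y_i - m(X_i,Z_i)) (Z_i - e(X_i)) / [e(X_i)(1 - e(X_i))]

with the counterfactual means recovered from the marginal mean and the CATE
via m(x,1) = m(x) + (1-e(x)) tau(x) and m(x,0) = m(x) - e(x) tau(x).

Weighted means of gamma estimate the ATE; restricting to a subgroup mask
gives the GATE; the ratio of outcome to treatment-uptake score means gives
the LATE with a delta-method clustered SE. All variances use the household
cluster sandwich: with household residual sums u_h = sum_{i in h} w_i
(gamma_i - estimate), SE = sqrt(sum_h u_h^2) / sum_i w_i.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AIPWScoreSet",
    "EffectEstimate",
    "aipw_scores",
    "average_effect",
    "group_average_effect",
    "late_effect",
    "standardized_difference",
    "balance_table",
]

Z975 = 1.96  # normal quantile for the symmetric 95% intervals


@dataclass
class AIPWScoreSet:
    """Per-person doubly robust scores for one outcome."""

    gamma: np.ndarray
    weights: np.ndarray
    households: np.ndarray
    label: str = ""
    n_dropped: int = 0
    row_index: np.ndarray | None = None  # original-sample row of each score

    def __post_init__(self):
        if not (len(self.gamma) == len(self.weights) == len(self.households)):
            raise ValueError("score components must be aligned")
        if not np.all(np.isfinite(self.gamma)):
            raise ValueError("AIPW scores must be finite")

    def __len__(self) -> int:
        return len(self.gamma)

    def restrict(self, mask: np.ndarray) -> "AIPWScoreSet":
        mask = np.asarray(mask, dtype=bool)
        return AIPWScoreSet(self.gamma[mask], self.weights[mask],
                            self.households[mask], label=self.label,
                            row_index=None if self.row_index is None
                            else self.row_index[mask])

    def mask_rows(self, sample_mask: np.ndarray) -> np.ndarray:
        """Translate a full-sample boolean mask to this score set's rows."""
        sample_mask = np.asarray(sample_mask, dtype=bool)
        if self.row_index is None:
            if len(sample_mask) != len(self):
                raise ValueError("mask must align with the score set")
            return sample_mask
        return sample_mask[self.row_index]


@dataclass
class EffectEstimate:
    """Point estimate with cluster-robust SE and symmetric 95% CI."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    n_persons: int
    n_households: int
    label: str = ""

    @property
    def p_value(self) -> float:
        """Two-sided normal p-value for H0: effect = 0."""
        if self.se == 0:
            return 0.0 if self.estimate != 0 else 1.0
        return float(2.0 * stats.norm.sf(abs(self.estimate) / self.se))

    def __str__(self) -> str:
        lab = f"{self.label}: " if self.label else ""
        return (f"{lab}{self.estimate:.4f} (95% CI {self.ci_low:.4f}, "
                f"{self.ci_high:.4f}; SE {self.se:.4f}; n={self.n_persons})")


def aipw_scores(y, z, m_hat, e_hat, cate_oob, weights, households,
                label: str = "", row_index=None) -> AIPWScoreSet:
    """Assemble doubly robust scores from OOB nuisances and OOB CATEs.

    Rows where any ingredient is missing (NaN) are dropped with a logged
    count; the propensity is assumed already clamped away from 0 and 1.
    """
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    m = np.asarray(m_hat, float)
    e = np.asarray(e_hat, float)
    tau = np.asarray(cate_oob, float)
    w = np.asarray(weights, float)
    hh = np.asarray(households)
    keep = np.isfinite(y) & np.isfinite(m) & np.isfinite(e) & np.isfinite(tau)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("aipw_scores: dropped %d rows with missing inputs", n_dropped)
    y, z, m, e, tau, w, hh = (a[keep] for a in (y, z, m, e, tau, w, hh))
    ridx = None if row_index is None else np.asarray(row_index)[keep]
    m1 = m + (1.0 - e) * tau
    m0 = m - e * tau
    m_z = np.where(z > 0.5, m1, m0)
    gamma = (m1 - m0) + (y - m_z) * (z - e) / (e * (1.0 - e))
    return AIPWScoreSet(gamma, w, hh, label=label, n_dropped=n_dropped, row_index=ridx)


def _cluster_stats(scores: AIPWScoreSet) -> tuple[float, float, int, int]:
    w = scores.weights
    g = scores.gamma
    sw = float(w.sum())
    est = float(np.sum(w * g) / sw)
    resid = w * (g - est)
    sums = pd.Series(resid).groupby(scores.households).sum().to_numpy()
    if len(sums) < 2:
        raise ValueError("cluster-robust SE undefined with a single household")
    se = float(np.sqrt(np.sum(sums ** 2)) / sw)
    return est, se, len(g), len(sums)


def average_effect(scores: AIPWScoreSet, label: str | None = None) -> EffectEstimate:
    """Survey-weighted mean of the scores with household-clustered SE."""
    if len(scores) == 0:
        raise ValueError("cannot average an empty score set")
    est, se, n, nh = _cluster_stats(scores)
    lab = scores.label if label is None else label
    return EffectEstimate(est, se, est - Z975 * se, est + Z975 * se, n, nh, label=lab)


def group_average_effect(scores: AIPWScoreSet, mask, label: str = "") -> EffectEstimate:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != scores.gamma.shape:
        raise ValueError("subgroup mask must align with the score set")
    if not mask.any():
        raise ValueError(f"subgroup {label or '<unnamed>'} is empty")
    return average_effect(scores.restrict(mask), label=label)


def align_scores(a: AIPWScoreSet, b: AIPWScoreSet) -> tuple[AIPWScoreSet, AIPWScoreSet]:
    """Restrict two score sets to their common original-sample rows."""
    if a.row_index is None or b.row_index is None:
        if len(a) != len(b):
            raise ValueError("score sets of different length and no row index to align on")
        return a, b
    common = np.intersect1d(a.row_index, b.row_index)
    return (a.restrict(np.isin(a.row_index, common)),
            b.restrict(np.isin(b.row_index, common)))


def late_effect(scores_y: AIPWScoreSet, scores_d: AIPWScoreSet,
                label: str = "") -> EffectEstimate:
    """Ratio of outcome to uptake score means: the complier (local) effect.

    SE by the delta method on the clustered covariance of the paired
    household score sums.
    """
    scores_y, scores_d = align_scores(scores_y, scores_d)
    if len(scores_y) != len(scores_d) or not np.array_equal(scores_y.households,
                                                            scores_d.households):
        raise ValueError("outcome and treatment score sets must be aligned")
    w = scores_y.weights
    sw = float(w.sum())
    a = float(np.sum(w * scores_y.gamma) / sw)   # ITT on the outcome
    b = float(np.sum(w * scores_d.gamma) / sw)   # ITT on uptake (first stage)
    if abs(b) < 1e-6:
        raise ValueError("weak instrument: first-stage effect is numerically zero")
    theta = a / b
    ry = pd.Series(w * (scores_y.gamma - a)).groupby(scores_y.households).sum().to_numpy()
    rd = pd.Series(w * (scores_d.gamma - b)).groupby(scores_d.households).sum().to_numpy()
    if len(ry) < 2:
        raise ValueError("cluster-robust SE undefined with a single household")
    var_a = np.sum(ry ** 2) / sw ** 2
    var_b = np.sum(rd ** 2) / sw ** 2
    cov = np.sum(ry * rd) / sw ** 2
    var_theta = (var_a - 2.0 * theta * cov + theta ** 2 * var_b) / b ** 2
    se = float(np.sqrt(max(var_theta, 0.0)))
    return EffectEstimate(theta, se, theta - Z975 * se, theta + Z975 * se,
                          len(scores_y), len(ry), label=label)


def _weighted_mean_var(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    sw = w.sum()
    mean = float(np.sum(w * x) / sw)
    var = float(np.sum(w * (x - mean) ** 2) / sw)
    return mean, var


def standardized_difference(values, group, weights=None) -> float:
    """Scale-free balance measure |x1 - x0| / sqrt((s1^2 + s0^2)/2).

    Binary variables use the p(1-p) variance; continuous variables the
    (weighted) sample variance.
    """
    x = np.asarray(values, float)
    g = np.asarray(group)
    w = np.ones_like(x) if weights is None else np.asarray(weights, float)
    m1 = g == 1
    m0 = ~m1
    if not m1.any() or not m0.any():
        raise ValueError("both groups must be nonempty")
    binary = np.isin(np.unique(x), (0.0, 1.0)).all()
    mu1, v1 = _weighted_mean_var(x[m1], w[m1])
    mu0, v0 = _weighted_mean_var(x[m0], w[m0])
    if binary:
        v1 = mu1 * (1.0 - mu1)
        v0 = mu0 * (1.0 - mu0)
    denom = np.sqrt((v1 + v0) / 2.0)
    if denom == 0:
        return 0.0
    return float(abs(mu1 - mu0) / denom)


def balance_table(sample, by: str = "Z", weighted: bool = True) -> pd.DataFrame:
    """Standardized differences of every covariate across the ``by`` groups."""
    g = sample.column(by)
    w = sample.weight if weighted else None
    rows = []
    for name in sample.covariate_names:
        col = sample.df[sample.COV_PREFIX + name].to_numpy(float)
        rows.append({"covariate": name, "by": by,
                     "std_diff": standardized_difference(col, g, w)})
    return pd.DataFrame(rows)
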