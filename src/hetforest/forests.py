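"""Honest regression, causal and instrumental forests.

Model objects follow the fit-then-results idiom: construct a model from a
sample (or raw arrays), call ``fit()``, and work with the returned results
object, which carries out-of-bag nuisances, OOB CATEs, predictions for new
points, variable importances and AIPW-based effect estimates.

Estimation pipeline for the causal forest:

1. regression forests for the marginal outcome mean m(x) and the
   assignment propensity e(x), both evaluated out-of-bag;
2. local centering Y - m^(-i), Z - e^(-i) (Robinson orthogonalization);
3. honest causal trees grown on household-level subsamples, splits chosen
   by the expected-MSE heterogeneity criterion on the split half, leaf
   effects re-estimated on the estimation half;
4. CATE prediction by the adaptive alpha-weighted residual-on-residual
   ratio across trees, out-of-bag for training households.

The instrumental forest replaces the causal ratio with the local IV ratio
(centered instrument times centered outcome over centered instrument times
centered treatment); with perfect compliance (D identical to Z) it reduces
exactly to the causal forest.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from . import _engine
from .datagen import ObservationalSample

logger = logging.getLogger(__name__)

__all__ = [
    "save_forest",
    "ForestParams",
    "NuisanceFit",
    "HonestTree",
    "CATEEstimates",
    "RegressionForest",
    "CausalForest",
    "InstrumentalForest",
    "fit_regression_forest",
    "fit_causal_forest",
    "fit_instrumental_forest",
    "center_sample",
    "grow_causal_tree",
    "predict_cate",
    "variable_importance",
]

E_CLAMP = (0.01, 0.99)


@dataclass
class ForestParams:
    """Hyperparameters shared by all forest flavours.

    n_trees: ensemble size B (full-scale analyses in the motivating study
        use 20,000; the default is a desk-scale 2,000).
    sample_fraction: household-level subsample drawn per tree.
    honesty_fraction: share of each subsample assigned to the split half.
    mtry: covariates tried per split; None -> ceil(sqrt(p)).
    min_node_size: minimum estimation-half count per leaf; for causal and
        instrumental trees the count applies to assigned and unassigned
        units separately.
    alpha_imbalance: each child must keep at least this fraction of the
        node's split-half observations.
    imbalance_penalty: nonnegative penalty on unbalanced splits.
    """

    n_trees: int = 2000
    sample_fraction: float = 0.5
    honesty_fraction: float = 0.5
    mtry: int | None = None
    min_node_size: int = 5
    alpha_imbalance: float = 0.05
    imbalance_penalty: float = 0.0
    max_depth: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not (0.0 < self.sample_fraction <= 1.0):
            raise ValueError("sample_fraction must be in (0, 1]")
        if not (0.0 < self.honesty_fraction < 1.0):
            raise ValueError("honesty_fraction must be in (0, 1)")
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")
        if not (0.0 < self.alpha_imbalance <= 0.25):
            raise ValueError("alpha_imbalance must be in (0, 0.25]")
        if self.imbalance_penalty < 0:
            raise ValueError("imbalance_penalty must be nonnegative")

    def resolved_mtry(self, p: int) -> int:
        m = self.mtry if self.mtry is not None else math.ceil(math.sqrt(p))
        return max(1, min(m, p))

    @classmethod
    def paper_scale(cls, **overrides) -> "ForestParams":
        """The full-scale configuration used in the motivating study."""
        return cls(n_trees=20000, **overrides)


@dataclass
class NuisanceFit:
    """Out-of-bag nuisance predictions aligned to the analysis sample."""

    m_hat: np.ndarray            # marginal outcome mean
    e_hat: np.ndarray            # assignment propensity, clamped
    e_hat_raw: np.ndarray
    d_hat: np.ndarray | None = None   # treatment propensity (IV only)
    n_clamped: int = 0


@dataclass
class HonestTree:
    """One honest tree as flat node arrays (feature < 0 marks a leaf)."""

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray
    num_mean: np.ndarray
    den_mean: np.ndarray
    cnt: np.ndarray
    inherited: np.ndarray
    est_rows: np.ndarray     # training-row indices of the estimation half (post-partition order)
    est_leaf: np.ndarray     # leaf node id per est row
    split_rows: np.ndarray   # training-row indices of the split half

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    def structure(self) -> tuple:
        """Hashable split structure (used by honesty/determinism checks)."""
        return (tuple(self.feature.tolist()), tuple(np.round(self.threshold, 12).tolist()),
                tuple(self.left.tolist()), tuple(self.right.tolist()))

    def root_split(self) -> tuple[int, float] | None:
        if self.feature[0] < 0:
            return None
        return int(self.feature[0]), float(self.threshold[0])

    def leaf_for(self, x: np.ndarray) -> int:
        node = 0
        while self.feature[node] >= 0:
            node = self.left[node] if x[self.feature[node]] <= self.threshold[node] else self.right[node]
        return int(node)


@dataclass
class CATEEstimates:
    """Per-query CATE predictions with the alpha-weight bookkeeping."""

    tau_hat: np.ndarray
    oob: bool
    trees_used: np.ndarray
    alpha_weights: np.ndarray | None = None

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.tau_hat)


# ---------------------------------------------------------------------------
# shared fitting machinery
# ---------------------------------------------------------------------------

@dataclass
class _FittedForest:
    mode: int
    trees: list[HonestTree]
    inbag: np.ndarray          # (n_trees, n_households) uint8
    hh_codes: np.ndarray       # per training row
    n_households: int
    X: np.ndarray
    y: np.ndarray              # centered outcome (or raw response, mode 0)
    zc: np.ndarray
    dc: np.ndarray
    w: np.ndarray
    treat: np.ndarray
    params: ForestParams
    _concat: tuple | None = None

    def concat(self):
        if self._concat is None:
            offs = np.zeros(len(self.trees) + 1, dtype=np.int64)
            for i, t in enumerate(self.trees):
                offs[i + 1] = offs[i] + t.n_nodes
            feat = np.concatenate([t.feature for t in self.trees])
            thr = np.concatenate([t.threshold for t in self.trees])
            left = np.concatenate([t.left for t in self.trees])
            right = np.concatenate([t.right for t in self.trees])
            num = np.concatenate([t.num_mean for t in self.trees])
            den = np.concatenate([t.den_mean for t in self.trees])
            self._concat = (feat, thr, left, right, num, den, offs)
        return self._concat

    def predict(self, Xq: np.ndarray, hh_q: np.ndarray | None = None,
                oob: bool = False) -> CATEEstimates:
        Xq = np.ascontiguousarray(Xq, dtype=np.float64)
        feat, thr, left, right, num, den, offs = self.concat()
        if oob:
            if hh_q is None:
                raise ValueError("oob prediction requires household codes for the query rows")
            hhq = np.ascontiguousarray(hh_q, dtype=np.int64)
        else:
            hhq = np.zeros(len(Xq), dtype=np.int64)
        num_acc, den_acc, used = _engine.predict_forest(
            feat, thr, left, right, num, den, offs, Xq, hhq, self.inbag, 1 if oob else 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            tau = np.where((used > 0) & (np.abs(den_acc) > 1e-12), num_acc / den_acc, np.nan)
        return CATEEstimates(tau_hat=tau, oob=oob, trees_used=used)

    def alpha_weights(self, x: np.ndarray) -> np.ndarray:
        """Spec-form alpha_i(x): average over trees of 1/|leaf| membership,
        over training rows, normalized to sum 1. Slow path for diagnostics."""
        n = len(self.X)
        alpha = np.zeros(n)
        for t in self.trees:
            leaf = t.leaf_for(np.asarray(x, dtype=float))
            members = t.est_rows[t.est_leaf == leaf]
            if len(members):
                alpha[members] += 1.0 / len(members)
        s = alpha.sum()
        return alpha / s if s > 0 else alpha


def _draw_tree_sample(rng: np.random.Generator, H: int, params: ForestParams):
    k = max(2, int(math.floor(params.sample_fraction * H))) if H >= 2 else H
    k = min(k, H)
    chosen = rng.permutation(H)[:k]
    n_split = int(math.floor(params.honesty_fraction * k))
    n_split = min(max(n_split, 1), k - 1) if k >= 2 else 1
    split_h = chosen[:n_split]
    est_h = chosen[n_split:]
    return chosen, split_h, est_h


def _fit_forest(mode: int, X: np.ndarray, y: np.ndarray, zc: np.ndarray,
                dc: np.ndarray, w: np.ndarray, treat: np.ndarray,
                hh_codes: np.ndarray, params: ForestParams, seed: int) -> _FittedForest:
    params.validate()
    X = np.ascontiguousarray(X, dtype=np.float64)
    n, p = X.shape
    H = int(hh_codes.max()) + 1 if n else 0
    mtry = params.resolved_mtry(p)
    ss = np.random.SeedSequence(entropy=seed)
    children = ss.spawn(params.n_trees)
    inbag = np.zeros((params.n_trees, H), dtype=np.uint8)
    trees: list[HonestTree] = []
    rows_by_hh = hh_codes  # alias
    for b, child in enumerate(children):
        rng = np.random.default_rng(child)
        chosen, split_h, est_h = _draw_tree_sample(rng, H, params)
        inbag[b, chosen] = 1
        is_split = np.zeros(H, dtype=bool)
        is_split[split_h] = True
        is_est = np.zeros(H, dtype=bool)
        is_est[est_h] = True
        sidx = np.flatnonzero(is_split[rows_by_hh]).astype(np.int64)
        eidx = np.flatnonzero(is_est[rows_by_hh]).astype(np.int64)
        kseed = int(child.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
        (feat, thr, left, right, value, num, den, cnt, inher, eout, leaf_of_est,
         n_nodes) = _engine.grow_tree(
            mode, X, y, zc, dc, w, treat, sidx, eidx, mtry,
            params.min_node_size, params.alpha_imbalance,
            params.imbalance_penalty, params.max_depth, kseed)
        trees.append(HonestTree(feat, thr, left, right, value, num, den, cnt,
                                inher, eout, leaf_of_est, sidx))
    return _FittedForest(mode=mode, trees=trees, inbag=inbag, hh_codes=hh_codes,
                         n_households=H, X=X, y=y, zc=zc, dc=dc, w=w,
                         treat=treat, params=params)


def _validate_inputs(*arrays):
    for a in arrays:
        if a is not None and not np.all(np.isfinite(a)):
            raise ValueError("input contains missing or non-finite values")


def _as_codes(clusters: np.ndarray | None, n: int) -> np.ndarray:
    if clusters is None:
        return np.arange(n, dtype=np.int64)
    _, codes = np.unique(np.asarray(clusters), return_inverse=True)
    return codes.astype(np.int64)


# ---------------------------------------------------------------------------
# regression forest
# ---------------------------------------------------------------------------

class RegressionForest:
    """Honest subsampled regression forest for nuisance functions."""

    def __init__(self, X, y, weights=None, clusters=None, params: ForestParams | None = None):
        self.X = np.ascontiguousarray(X, dtype=np.float64)
        self.y = np.asarray(y, dtype=np.float64)
        n = len(self.y)
        self.w = np.ones(n) if weights is None else np.asarray(weights, dtype=np.float64)
        self.hh = _as_codes(clusters, n)
        self.params = params or ForestParams()
        _validate_inputs(self.X, self.y, self.w)
        if n < 2 * self.params.min_node_size:
            raise ValueError("need at least 2*min_node_size observations")

    def fit(self, seed: int | None = None) -> "RegressionForestResults":
        seed = self.params.seed if seed is None else seed
        zeros = np.zeros(len(self.y))
        treat = np.ones(len(self.y), dtype=np.int64)
        ff = _fit_forest(0, self.X, self.y, zeros, zeros, self.w, treat,
                         self.hh, self.params, seed)
        return RegressionForestResults(self, ff)


class RegressionForestResults:
    def __init__(self, model: RegressionForest, forest: _FittedForest):
        self.model = model
        self.forest = forest

    def predict(self, Xq) -> np.ndarray:
        return self.forest.predict(np.asarray(Xq, dtype=np.float64)).tau_hat

    def predict_oob(self) -> np.ndarray:
        """OOB prediction per training row; NaN where no tree excludes the row's household."""
        est = self.forest.predict(self.model.X, hh_q=self.model.hh, oob=True)
        return est.tau_hat


# ---------------------------------------------------------------------------
# centering
# ---------------------------------------------------------------------------

def center_sample(y: np.ndarray, z: np.ndarray, nuisance: NuisanceFit,
                  d: np.ndarray | None = None):
    """Residualize outcome and assignment (and treatment for IV) by OOB nuisances.

    Rows with missing OOB predictions are excluded via the returned ``keep``
    mask; the caller logs the count.
    """
    keep = np.isfinite(nuisance.m_hat) & np.isfinite(nuisance.e_hat)
    if nuisance.d_hat is not None:
        keep &= np.isfinite(nuisance.d_hat)
    yc = y - nuisance.m_hat
    zc = z - nuisance.e_hat
    dc = None if d is None else d - (nuisance.d_hat if nuisance.d_hat is not None else nuisance.e_hat)
    return yc, zc, dc, keep


def _clamp_propensity(e_raw: np.ndarray) -> tuple[np.ndarray, int]:
    lo, hi = E_CLAMP
    fin = np.isfinite(e_raw)
    n_out = int(((e_raw[fin] < lo) | (e_raw[fin] > hi)).sum())
    e = np.where(fin, np.clip(e_raw, lo, hi), e_raw)
    if n_out:
        warnings.warn(f"{n_out} propensity predictions clamped to [{lo}, {hi}]",
                      RuntimeWarning, stacklevel=3)
    return e, n_out


# ---------------------------------------------------------------------------
# causal / instrumental forest models
# ---------------------------------------------------------------------------

_STREAM_TREES, _STREAM_OUTCOME, _STREAM_ASSIGN = 0, 1, 2


def _sub_seed(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(stream,))
               .generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


class CausalForest:
    """Honest causal forest for the effect of a (randomized) binary assignment.

    Parameters
    ----------
    sample : ObservationalSample
    outcome : outcome name, or one of "D"/"applied"/"approved" for the
        uptake-funnel analyses.
    treatment : the assignment column (the lottery draw "Z" for
        intent-to-treat analyses).
    """

    def __init__(self, sample: ObservationalSample, outcome: str,
                 treatment: str = "Z", params: ForestParams | None = None):
        self.sample = sample
        self.outcome_name = outcome
        self.treatment_name = treatment
        self.params = params or ForestParams()
        self.X = sample.X
        self.y = sample.column(outcome)
        self.z = sample.column(treatment)
        self.w = sample.weight
        self.hh = _as_codes(sample.household_id, sample.n)
        _validate_inputs(self.X, self.y, self.z, self.w)

    # -- nuisance step -------------------------------------------------
    def _fit_nuisance(self, seed: int) -> NuisanceFit:
        m_res = RegressionForest(self.X, self.y, self.w, self.hh,
                                 replace(self.params)).fit(_sub_seed(seed, _STREAM_OUTCOME))
        e_res = RegressionForest(self.X, self.z, self.w, self.hh,
                                 replace(self.params)).fit(_sub_seed(seed, _STREAM_ASSIGN))
        m_hat = m_res.predict_oob()
        e_raw = e_res.predict_oob()
        e_hat, n_clamped = _clamp_propensity(e_raw)
        return NuisanceFit(m_hat=m_hat, e_hat=e_hat, e_hat_raw=e_raw, n_clamped=n_clamped)

    def fit(self, seed: int | None = None,
            nuisance: NuisanceFit | None = None) -> "CausalForestResults":
        seed = self.params.seed if seed is None else seed
        if nuisance is None:
            nuisance = self._fit_nuisance(seed)
        yc, zc, _, keep = center_sample(self.y, self.z, nuisance)
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("dropping %d rows with missing OOB nuisance predictions", n_drop)
        idx = np.flatnonzero(keep)
        hh_kept = _as_codes(self.hh[idx], len(idx))
        treat = (self.z[idx] > 0.5).astype(np.int64)
        zck = zc[idx]
        ff = _fit_forest(1, self.X[idx], yc[idx], zck, zck, self.w[idx], treat,
                         hh_kept, self.params, _sub_seed(seed, _STREAM_TREES))
        return CausalForestResults(self, ff, nuisance, idx, seed)


class InstrumentalForest(CausalForest):
    """Honest instrumental forest: effect of treatment D identified by instrument Z."""

    def __init__(self, sample: ObservationalSample, outcome: str,
                 treatment: str = "D", instrument: str = "Z",
                 params: ForestParams | None = None):
        super().__init__(sample, outcome, treatment=instrument, params=params)
        self.instrument_name = instrument
        self.d = sample.column(treatment)
        self.d_name = treatment
        _validate_inputs(self.d)

    def _fit_nuisance(self, seed: int) -> NuisanceFit:
        nui = super()._fit_nuisance(seed)
        d_res = RegressionForest(self.X, self.d, self.w, self.hh,
                                 replace(self.params)).fit(_sub_seed(seed, _STREAM_ASSIGN))
        nui.d_hat = d_res.predict_oob()
        return nui

    def fit(self, seed: int | None = None,
            nuisance: NuisanceFit | None = None) -> "CausalForestResults":
        seed = self.params.seed if seed is None else seed
        if nuisance is None:
            nuisance = self._fit_nuisance(seed)
        yc, zc, dc, keep = center_sample(self.y, self.z, nuisance, d=self.d)
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("dropping %d rows with missing OOB nuisance predictions", n_drop)
        idx = np.flatnonzero(keep)
        hh_kept = _as_codes(self.hh[idx], len(idx))
        treat = (self.z[idx] > 0.5).astype(np.int64)
        ff = _fit_forest(1, self.X[idx], yc[idx], zc[idx], dc[idx], self.w[idx],
                         treat, hh_kept, self.params, _sub_seed(seed, _STREAM_TREES))
        return CausalForestResults(self, ff, nuisance, idx, seed)


class CausalForestResults:
    """Fitted causal/instrumental forest: OOB CATEs, predictions, importances.

    Effect aggregation (ATE/GATE/LATE via AIPW scores) lives in
    :mod:`hetforest.estimation` and is exposed through ``aipw_scores``,
    ``ate`` and ``gate`` here for convenience.
    """

    def __init__(self, model: CausalForest, forest: _FittedForest,
                 nuisance: NuisanceFit, kept_idx: np.ndarray, seed: int):
        self.model = model
        self.forest = forest
        self.nuisance = nuisance
        self.kept_idx = kept_idx
        self.seed = seed
        self._cate_oob: CATEEstimates | None = None

    # -- prediction ----------------------------------------------------
    def predict(self, Xq, oob: bool = False) -> CATEEstimates:
        if oob:
            return self.cate_oob_estimates()
        return self.forest.predict(np.asarray(Xq, dtype=np.float64))

    def cate_oob_estimates(self) -> CATEEstimates:
        if self._cate_oob is None:
            self._cate_oob = self.forest.predict(self.forest.X,
                                                 hh_q=self.forest.hh_codes, oob=True)
        return self._cate_oob

    @property
    def cate_oob(self) -> np.ndarray:
        """OOB CATE per *kept* analysis row (NaN where not estimable)."""
        return self.cate_oob_estimates().tau_hat

    def alpha_weights(self, x) -> np.ndarray:
        return self.forest.alpha_weights(np.asarray(x, dtype=float))

    # -- kept-row views of the analysis sample -------------------------
    @property
    def y(self) -> np.ndarray:
        return self.model.y[self.kept_idx]

    @property
    def z(self) -> np.ndarray:
        return self.model.z[self.kept_idx]

    @property
    def w(self) -> np.ndarray:
        return self.model.w[self.kept_idx]

    @property
    def households(self) -> np.ndarray:
        return self.model.hh[self.kept_idx]

    @property
    def m_hat(self) -> np.ndarray:
        return self.nuisance.m_hat[self.kept_idx]

    @property
    def e_hat(self) -> np.ndarray:
        return self.nuisance.e_hat[self.kept_idx]

    # -- effect aggregation --------------------------------------------
    def aipw_scores(self):
        from .estimation import aipw_scores
        return aipw_scores(self.y, self.z, self.m_hat, self.e_hat,
                           self.cate_oob, self.w, self.households,
                           label=self.model.outcome_name, row_index=self.kept_idx)

    def ate(self):
        from .estimation import average_effect
        return average_effect(self.aipw_scores())

    def gate(self, mask: np.ndarray, label: str = ""):
        """GATE for a full-sample boolean mask."""
        from .estimation import group_average_effect
        scores = self.aipw_scores()
        return group_average_effect(scores, scores.mask_rows(np.asarray(mask, bool)),
                                    label=label)

    # -- importance ----------------------------------------------------
    def variable_importance(self, decay_exponent: float = 2.0, max_depth: int = 4) -> np.ndarray:
        return variable_importance(self.forest, decay_exponent, max_depth)

    def summary(self) -> str:
        est = self.ate()
        lines = [
            f"Causal forest: outcome={self.model.outcome_name!r} "
            f"assignment={self.model.treatment_name!r}",
            f"  trees={self.forest.params.n_trees}  n={len(self.kept_idx)}  "
            f"households={self.forest.n_households}",
            f"  ATE (AIPW) = {est.estimate:.4f}  SE = {est.se:.4f}  "
            f"95% CI = ({est.ci_low:.4f}, {est.ci_high:.4f})",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# variable importance and serialization
# ---------------------------------------------------------------------------

def variable_importance(forest: _FittedForest, decay_exponent: float = 2.0,
                        max_depth: int = 4) -> np.ndarray:
    """Depth-weighted split-frequency importance, normalized to sum 1.

    score_j  ∝  sum_{d=1..max_depth} d^(-decay) * splits_j(d) / splits_total(d)
    """
    p = forest.X.shape[1]
    counts = np.zeros((max_depth + 1, p))
    for tree in forest.trees:
        depth = np.zeros(tree.n_nodes, dtype=np.int64)
        for node in range(tree.n_nodes):
            if tree.feature[node] >= 0:
                d = depth[node] + 1  # depth of this split, root split = depth 1
                depth[tree.left[node]] = d
                depth[tree.right[node]] = d
                if d <= max_depth:
                    counts[d, tree.feature[node]] += 1.0
    score = np.zeros(p)
    total_splits = counts.sum()
    if total_splits == 0:
        warnings.warn("forest has no splits; importance is uniform", RuntimeWarning)
        return np.full(p, 1.0 / p)
    for d in range(1, max_depth + 1):
        tot = counts[d].sum()
        if tot > 0:
            score += d ** (-decay_exponent) * counts[d] / tot
    s = score.sum()
    return score / s if s > 0 else np.full(p, 1.0 / p)


def save_forest(forest: _FittedForest, path) -> None:
    """Serialize a fitted forest to JSON lines (params header + one tree per line)."""
    with open(path, "w") as fh:
        header = {"mode": forest.mode, "n_households": forest.n_households,
                  "params": asdict(forest.params)}
        fh.write(json.dumps(header) + "\n")
        for b, t in enumerate(forest.trees):
            rec = {
                "feature": t.feature.tolist(),
                "threshold": t.threshold.tolist(),
                "left": t.left.tolist(),
                "right": t.right.tolist(),
                "value": t.value.tolist(),
                "num_mean": t.num_mean.tolist(),
                "den_mean": t.den_mean.tolist(),
                "cnt": t.cnt.tolist(),
                "inbag": np.flatnonzero(forest.inbag[b]).tolist(),
            }
            fh.write(json.dumps(rec) + "\n")


# ---------------------------------------------------------------------------
# functional wrappers (thin layers over the model objects)
# ---------------------------------------------------------------------------

def fit_regression_forest(features, response, weights=None, clusters=None,
                          params: ForestParams | None = None,
                          seed: int | None = None) -> RegressionForestResults:
    return RegressionForest(features, response, weights, clusters, params).fit(seed)


def fit_causal_forest(sample: ObservationalSample, outcome: str,
                      params: ForestParams | None = None, seed: int | None = None,
                      treatment: str = "Z") -> CausalForestResults:
    return CausalForest(sample, outcome, treatment=treatment, params=params).fit(seed)


def fit_instrumental_forest(sample: ObservationalSample, outcome: str,
                            params: ForestParams | None = None,
                            seed: int | None = None) -> CausalForestResults:
    return InstrumentalForest(sample, outcome, params=params).fit(seed)


def predict_cate(results: CausalForestResults, Xq, oob: bool = False) -> CATEEstimates:
    return results.predict(Xq, oob=oob)


def grow_causal_tree(X, yc, zc, w, treat, split_idx, est_idx,
                     params: ForestParams | None = None, seed: int = 0,
                     dc=None) -> HonestTree:
    """Grow a single honest causal tree with pre-assigned halves."""
    params = params or ForestParams()
    params.validate()
    X = np.ascontiguousarray(X, dtype=np.float64)
    yc = np.asarray(yc, dtype=np.float64)
    zc = np.asarray(zc, dtype=np.float64)
    dcv = zc if dc is None else np.asarray(dc, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    treat = np.asarray(treat, dtype=np.int64)
    sidx = np.asarray(split_idx, dtype=np.int64)
    eidx = np.asarray(est_idx, dtype=np.int64)
    if len(set(sidx.tolist()) & set(eidx.tolist())):
        raise ValueError("split and estimation halves must be disjoint")
    mtry = params.resolved_mtry(X.shape[1])
    (feat, thr, left, right, value, num, den, cnt, inher, eout, leaf_of_est,
     n_nodes) = _engine.grow_tree(
        1, X, yc, zc, dcv, w, treat, sidx, eidx, mtry, params.min_node_size,
        params.alpha_imbalance, params.imbalance_penalty, params.max_depth, seed)
    return HonestTree(feat, thr, left, right, value, num, den, cnt, inher,
                      eout, leaf_of_est, sidx)
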