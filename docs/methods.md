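# Methods

This note documents the models and procedures implemented in `hetforest`,
the design choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Estimands and identification

The package targets effects of a *randomized* binary assignment `Z`
(lottery selection) on outcomes `Y`, and — through the instrument — effects
of an endogenous binary treatment `D` (insurance enrollment). Person-level
effects `tau_i = Y_i(1) - Y_i(0)` are aggregated into the ATE, the
covariate-conditional CATE `tau(x)`, and prespecified-subgroup GATEs.
Because selection confers only the right to apply, `D` follows a funnel
(`applied -> approved -> enrolled`) and compliance is one-sided apart from
a small control crossover. Complier (LATE) effects are identified by the
instrument ratio.

## Honest causal forest

**Nuisances.** Honest subsampled regression forests estimate the marginal
outcome mean `m(x)` and the assignment propensity `e(x)`. Both are
evaluated out-of-bag: a prediction for row *i* uses only trees whose
household-level subsample excluded *i*'s household. Propensities are
clamped to [0.01, 0.99] (clamping is preferred to dropping rows because the
design is randomized and extreme fitted propensities are estimation noise,
not genuine overlap failure). Rows with no out-of-bag prediction are
dropped with a logged count.

**Tree growth.** Each tree subsamples households (default fraction 0.5),
splits them into a split half and an estimation half (honesty fraction
0.5, also at household level so the halves are independent given the
design), and grows greedily. Candidate thresholds are midpoints between
consecutive distinct split-half values; the left child takes `x <= t`.
A candidate is valid if each child keeps at least `alpha_imbalance` of the
node's split-half rows, at least one treated and one control split-half
row, `min_node_size` treated *and* control estimation-half rows (the
minimum-size rule is interpreted per assignment arm, so every leaf effect
is estimable), and a non-degenerate leaf denominator. Among valid
candidates the split maximizing the expected-MSE heterogeneity criterion
(split-half weighted leaf-effect squares minus `(1/N_tr + 1/N_est)` times
the per-arm within-leaf variance terms, with the node-level treated share
`p`) is taken; ties break to the lowest covariate index, then the lowest
threshold, making growth fully deterministic given the seed.

Causal/instrumental nodes split whenever a valid candidate exists: an
improvement-over-parent gate was evaluated and rejected because with few
covariates tried per node (`mtry = ceil(sqrt(p))`) it stops a large share
of trees at the root whenever the informative covariate misses the draw
(noise splits are nearly criterion-neutral), which measurably attenuates
CATE recovery toward the pooled effect. Regression trees keep the standard
CART rule (split only on strict SSE improvement), which leaves genuinely
constant responses as single leaves. Stopping is otherwise governed by the
size, arm-count and imbalance constraints.

**Leaf effects and prediction.** Leaf effects are re-estimated on the
estimation half as the weighted residual-on-residual ratio; a leaf with a
degenerate denominator inherits its parent's estimate (flagged). The CATE
at `x` uses leaf co-membership weights `alpha_i(x)` (average over trees of
`1/|leaf|` for estimation-half members of `x`'s leaf, normalized). The
printed estimator carries no survey weight inside the alpha-ratio, but the
within-leaf estimator is weighted; we fold `w` into the numerator and
denominator of the ratio so that a single-leaf tree reproduces the weighted
root ratio exactly and survey design is honored at every level. Per-point
CATE variances are *not* estimated; inference flows exclusively through
AIPW score averages.

**Instrumental forest.** Identical machinery with three centering forests
(`Y`, `D`, `Z`) and the local IV ratio
`sum w (Z - z)(Y - y) / sum w (Z - z)(D - d)` as the leaf estimator and
prediction target. The causal forest is implemented as the `D := Z` special
case of the same kernel, so under perfect compliance the two estimators
coincide bit-for-bit.

**Variable importance.** Depth-weighted split frequencies:
`score_j ∝ sum_d d^(-2) * splits_j(d) / splits_total(d)` over depths 1–4,
normalized to sum 1. The two-stage pipeline refits on covariates whose
importance exceeds 20% of the mean importance.

## AIPW estimation and inference

Counterfactual means are recovered from the marginal mean and the CATE via
`m(x,1) = m(x) + (1-e(x)) tau(x)`, `m(x,0) = m(x) - e(x) tau(x)`; scores
follow the doubly robust form and are averaged with survey weights.
Cluster-robust SEs use the household-sum sandwich without small-sample
degrees-of-freedom correction; 95% intervals are normal (±1.96 SE). GATEs
are the same average on subgroup rows, and share-weighted GATEs over any
partition recombine to the ATE exactly (asserted in the report writer).
LATE inference uses the delta method on the ratio of clustered score means.
No multiplicity correction is applied; the report carries a
documentation-only Bonferroni flag column.

## Heterogeneity diagnostics

**Calibration test.** Weighted regression of `Y - m` on
`(Z - e) * taubar` and `(Z - e) * (tau_oob - taubar)` with
household-clustered covariance (via statsmodels WLS); `alpha` near 1 means
the average prediction is calibrated, a one-sided positive `beta` indicates
real ranking information. Two variants are provided. The default uses the
forest's own out-of-bag CATEs, matching full-scale practice; at desk-scale
sample sizes under a *homogeneous* truth this variant is conservative,
because every other row's OOB CATE embeds row *i*'s residual product and
the resulting leakage tilts `beta` negative when true CATE variation is
zero. `calibration_test_crossfit` removes the leakage by predicting CATEs
with a forest fit on the opposite household half; its null t-statistic is
close to standard normal at these sizes, and it is the variant exercised by
the type-I-error validation study. Constant CATE predictions make `beta`
non-estimable; it is flagged and `alpha` is still returned.

**TOC / RATE.** `TOC(q)` is the weighted mean AIPW score among the top-`q`
weight fraction ranked by a priority rule minus the overall mean; tie
groups contribute their weighted mean score (so an uninformative constant
priority gives an identically zero curve). RATE integrates the curve by
trapezoid over a 100-point grid on (0, 1] with AUTOC weighting by default
(Qini = `q * TOC(q)` by flag). `rate_with_se` repeats
{fit on one household half, rank the other, score on the evaluation half's
own forest} over half-splits and reports the mean and the empirical SE
across splits. Priority and evaluation scores must come from disjoint
halves; the contract is documented, not enforced, for the low-level
`toc_curve`.

## Hyperparameter tuning

Random search over sample fraction (0.2–0.5), honesty fraction (0.4–0.6),
`mtry` (1–p), minimum node size (log-uniform 5–50), imbalance alpha
(0.01–0.25) and imbalance penalty (0 with probability ½, else uniform
0–2), scored by the out-of-bag R-loss `½ [Yc - tau(x) Zc]²` of small
forests. Nuisance fits are shared across candidates (only the causal trees
are regrown), a simplification relative to refitting everything per
candidate. The default parameter vector is always candidate 0, so tuning
can never degrade the objective relative to the defaults. The desk-scale
budget is 50 draws with 200-tree forests; `paper_scale` presets restore the
full-scale budgets (5,000 draws, ≥500-tree forests, 20,000-tree final
fits).

## Synthetic data generator

The generator emulates the design features that matter for the estimators:
household-level lottery randomization (sizes 1–3, all members share `Z`),
19 binary/indicator baseline covariates with marginal prevalences matched
to the motivating study's baseline table (race drawn categorically with an
independent other-race flag; a dropped reference level keeps 19 indicator
columns), a logistic application stage and a logistic approval stage with
marginal rates 64.1% and 47.8%, 2% control crossover, lognormal survey
weights normalized to mean 1 (σ = 0.3 where weighted designs are
exercised; unit weights otherwise), and eight outcomes across three
families — gaussian component scores, a Bernoulli-spend × lognormal-amount
spending outcome, and Poisson counts with additive treatment shifts on the
mean — so that in every family `E[Y | X, A] = baseline(X) + A·tau(X)` and
the configured `tau` is the exact person-level truth. Effects act through
`Z` (ITT channel) or through `D` (treatment channel) as configured.

It does **not** emulate: correlated comorbidities (covariates are
independent, so the derived high-risk share is higher than the study's
27%), covariate-dependent survey non-response, the study's wave/draw
structure, or its exact outcome distributions. Passing tests therefore
demonstrate the estimators' operating characteristics under a faithful
*design*, not distributional realism of any particular dataset.

All randomness flows from one root seed through named `SeedSequence`
streams (households, lottery, covariates, funnel, crossover, weights,
per-outcome noise), so extending a config does not perturb unrelated draws
and every artifact is byte-reproducible given (config, seed).

## Validation-study problem sizes

The simulation studies behind the acceptance checks use desk-scale sizes
chosen so the whole suite runs in minutes on one CPU, while keeping each
band meaningfully testable: split-search oracle on 200 instances with
n ≤ 30, p ≤ 3; ATE bias/coverage with 200 replicates of ~1,900 persons in
1,500 households and 150-tree forests; double robustness with 200
replicates of ~2,000 persons (score-level study, no forests needed); LATE
recovery at ~4,000 persons with 200-tree forests; calibration size with
200 replicates of ~1,000 persons and 100-tree forests. Tree counts enter
the estimators only through Monte Carlo smoothness of the CATE, and the
AIPW aggregates are insensitive to ensemble size well below the full-scale
20,000 trees.

## Known limitations

* No per-point CATE confidence intervals (bootstrap-of-little-bags is not
  implemented); all inference is for (sub)population averages.
* Trees reject missing values rather than handling them internally.
* The within-forest calibration test is conservative under weak
  heterogeneity at small n (see above); use the cross-fitted variant when
  the sample is modest.
* The IV analysis assumes no essential heterogeneity (no selection on
  gains among compliers) and inherits the usual power loss of instrument
  ratios; subgroup LATE intervals are wide at desk scale.
* Tuning evaluates candidates against shared nuisance fits; at full scale
  a per-candidate refit could select slightly different parameters.
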