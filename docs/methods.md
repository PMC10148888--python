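# Methods

This note records the statistical model behind `pwmmrm`, the defaults and
why they were chosen, what the synthetic-trial generator does and does not
emulate, and the numerical decisions a maintainer would want to know.

## Response definition and thresholds

A placebo responder is a subject whose total score at the end-of-study
visit has dropped by at least a clinically anchored fraction of baseline.
The shipped thresholds are constants: 0.38 for MADRS and 0.41 for HAMD-17.
The MADRS value sits between the mean percent reductions observed at CGI-I
"minimally improved" (24.5%) and "much improved" (52.5%); the arithmetic
midpoint of those anchors is 38.5%, and `derive_threshold_from_anchors`
computes it, but the shipped default is 38% — the value conventionally
used — with the computed midpoint retained on the `ThresholdSpec` for
audit. The HAMD-17 threshold of 41% is the equipercentile equivalent of
the 38% MADRS reduction; the linking sample behind that equivalence is not
redistributable, so the package ships the constant and provides
`equipercentile_link` (mid-rank percentile ranks, linear interpolation
between discrete score levels, clamped to the observed target range) so
users with their own linking samples can re-derive or replace it.

Subjects missing the end-of-study visit are excluded from label-dependent
steps by default (observed-case); a last-observation-carried-forward mode
exists because both conventions are common in this literature. They are
never excluded from the MMRM, which uses whatever visits they have.

## Propensity network

The classifier is a small multilayer perceptron: logistic activations in
all layers, a single logistic output, inputs standardized with training-set
statistics stored in the model. Choices that matter:

* **Loss** — binary cross-entropy by default (the natural likelihood for a
  probability output); sum-of-squares is selectable for parity with older
  neural-network tooling in this area.
* **Optimizer** — deterministic full-batch steepest descent with an Armijo
  backtracking line search (`step0 = 1`, halving, c = 1e-4). At n ≈ 100
  subjects this converges in well under a second, the loss trace is
  monotone by construction, and the run is exactly reproducible from a
  seed — which matters because the fitted probabilities become analysis
  weights. Stochastic minibatching buys nothing at this scale.
* **Ridge penalty** — `l2 = 0.01` on connection weights. With ~100
  training subjects and 17 features, an essentially unpenalized network
  saturates its outputs at 0/1; the moderate default keeps probabilities
  usable while costing nothing measurable in discrimination.
* **Topology search** — validation AUC over an exhaustive candidate list;
  default grid is every single-layer width 1–17 plus two- and three-layer
  "funnels" (k, ⌈k/2⌉[, ⌈k/4⌉]). Deeper exhaustive grids are accepted via
  config. Ties (within 1e-12) go to fewer total nodes, then fewer layers:
  prefer the smallest network that predicts equally well. Each candidate
  trains with a seed derived deterministically from the master seed and its
  grid position, so the *selection* is reproducible, not just the winner.
* **Validation** — case-resampling bootstrap of the held-out AUC,
  percentile interval, 1000 replicates by default; single-class resamples
  are redrawn. The interval is widened to contain the point estimate if a
  finite-sample percentile quirk would otherwise exclude it.
* **Weights** — `w = 1 / clip(p, 0.05, 1)`. Inverting raw probabilities is
  available (`p_min = 0`), but near-zero predicted probabilities produce
  unbounded weights, and the sensitivity analysis itself shows the low-
  propensity tail is influential; the clip is a guarded default, not a
  hidden truncation — it is recorded in the propensity table.

## Weighted MMRM

The longitudinal model for the change from baseline is a classical MMRM: a
fixed-effects generalized-least-squares model with one shared unstructured
T×T within-subject covariance Σ, fit by REML. "Random effect model with an
unstructured covariance" descriptions in the applied literature reduce to
this: a subject random intercept is subsumed by unstructured Σ, so no
separate random effect is added.

* **Fixed effects** (full-rank cell-style coding): one intercept per
  visit (the placebo mean), treatment×visit indicators with placebo as
  reference — so the treatment×visit coefficient *is* the adjusted
  treatment effect at that visit — a grand-mean-centered baseline
  covariate, and baseline×visit terms for visits after the first.
* **Weights** divide the residual covariance: `V_i = Σ_obs(i)/w_i`, the
  convention of standard weighted mixed-model software. Weights are
  normalized to mean one internally; this leaves every estimate invariant
  (Σ absorbs the scale) and makes "identical weights for everyone" exactly
  equivalent to an unweighted analysis, down to floating-point noise.
* **Estimation** — Σ is parameterized by its Cholesky factor with log
  diagonal (every iterate positive definite), the restricted likelihood is
  profiled over β, and L-BFGS-B with the analytic gradient runs first.
  Because downstream checks demand invariance at the 1e-8 level, a damped
  Newton polish follows: the observed information (central differences of
  the analytic gradient, h = 1e-5) is computed once and reused for Newton
  steps until the gradient norm falls below ~1e-11. The same information
  matrix then serves the Satterthwaite computation at no extra cost.
  Convergence is declared at gradient norm < 1e-6; a non-converged first
  attempt triggers one ridge restart (diagonal of Σ inflated) before the
  fit is returned flagged.
* **Start** — diagonal Σ⁰ from unweighted per-visit OLS residual
  variances: scale-aware and cheap.
* **Degrees of freedom** — Satterthwaite by default
  (`df = 2(c'Cc)²/(g'H⁻¹g)` with g the finite-difference gradient of the
  contrast variance in the covariance parameters), "residual"
  (N_obs − rank X) by switch. The applied reports this package mirrors do
  not state their df method; Satterthwaite is the defensible default at
  trial sizes, and the switch exists for exact replication of software
  that defaults to residual df.
* **LS means** are predictions at the grand-mean baseline; the treatment
  effect is their difference, and the standardized effect size divides
  |TE| by the pooled SD reconstructed as `SE / sqrt(1/n₁ + 1/n₂)` with
  n the per-arm subjects contributing to the fit.
* **Degenerate inputs** — visits observed for no subject are dropped with
  a warning; all-zero design columns (empty arm×visit cells) are pruned so
  X stays full rank, and contrasts touching a pruned cell raise; subjects
  with no post-baseline visits are dropped and counted.

## Sensitivity grid and bias metric

Six analyses per dose comparison: `{weighted, unweighted} × {all, drop
p < 0.2, drop p > 0.8}`. The low cut is 0.2 (the cut used in the tabulated
sensitivity layouts this grid mirrors; some prose descriptions say 0.1 — 
the cut is a config knob). The bias metric averages
`|TE_subset − TE_all| / |TE_all|` over both dose comparisons and both
subsets — four terms per weighting scheme; this averaging convention
reproduces the reference values 1.13 (unweighted) and 0.164 (weighted)
computed from the bundled example table to the printed precision. A subset
that empties an arm is flagged infeasible and the grid continues.

## Synthetic-trial generator

The generator exists because no public dataset pairs item-level
pre-randomization drift with post-randomization outcomes. It encodes the
simplest mechanism with the property the method assumes: one latent
propensity per subject expressed both before and after randomization.

* π_i ~ Beta(a, b); default (2, 2). `confounded_config()` switches to the
  U-shaped Beta(0.8, 0.3), concentrating mass above 0.8 (the pattern that
  inflates a placebo arm) while keeping a low tail so that removing
  low-propensity subjects is a meaningful perturbation.
* Screening totals are drawn per arm (normal, rounded) with the mean
  inflated by 1/(1 − κ·E[π]) so that the expected *baseline* totals hit
  the default calibration 23.13/23.51/23.81 (SD ≈ 3) at the default census
  156/154/149; totals are allocated to the 17 items by a capacity-
  respecting multinomial.
* Screening→baseline drift: an integer total drift with mean −κ·π_i·S_i
  (κ = 0.12; SD 1.5 points) removed point-by-point from the items, plus
  Poisson(4) zero-sum one-point swaps between items. Drawing the *total*
  first keeps the baseline calibration unbiased (per-item rounding against
  the 0 floor would otherwise bias totals upward); the swaps provide
  item-level scatter with no propensity information. κ = 0 yields the
  exact no-signal null.
* Post-baseline change: placebo component −(0.10 + 0.55·π_i)·B_i·
  (1 − e^(−t/2.5)) (asymptotic fractional improvement increasing in
  propensity, ~2.5-week time constant), plus a drug component
  `d_arm·(t/8)·(1 − placebo fraction)` — additive in time but attenuated
  where the placebo response already fills the room for improvement. This
  ceiling interaction is the confounding the weighting corrects: the
  *realized* drug effect is smaller in high-propensity subjects, so the
  per-arm mean realized effect (reported as the ground-truth TE) is
  attenuated relative to d_arm, and the unweighted estimate tracks that
  attenuated value while the weighted one recovers the effect in the
  low-propensity stratum.
* Residual noise is compound-symmetric (SD 4 points, correlation 0.5) —
  deliberately *not* the unstructured covariance the analysis model
  assumes, so tests exercise the realistic mis-specified case; an explicit
  `resid_cov` override provides the matched-covariance mode for exact
  oracle work. Totals are rounded and clamped to the scale range after
  noise addition; monotone dropout applies a 3% per-visit hazard.

What the generator does **not** emulate: site effects, visit-window
jitter, item-level trajectories after baseline (only totals are
generated), non-monotone missingness, and any dependence of dropout on
outcome (missingness is completely at random, stronger than the MAR
assumption the MMRM needs). Passing tests therefore demonstrate the
machinery and the confounding mechanism, not performance on real trial
data.

## Problem sizes used in the automated checks

The statistical suites run at deliberately scaled-down sizes chosen to
keep the full test run fast while leaving the assertions well-powered:
type-I error uses 500 replicates of a 150-subject, three-visit null trial;
the confounded-weighting directions use 200 replicates of the same census
with a fixed (6,) network; the no-signal null uses 50 replicates with an
80-subject placebo arm; the REML oracle comparisons use two-arm trials of
14–20 subjects, where the dense reference optimizer is exact and fast.

## Known limitations

* The MMRM treats the estimated weights as fixed; no uncertainty from the
  propensity model propagates into the treatment-effect standard errors
  (this matches how the analysis is run in practice, but the p-values are
  conditional on the weights).
* Kenward–Roger df, covariance structures other than unstructured, and
  multiple-imputation sensitivity analyses are out of scope.
* The equipercentile machinery implements the unsmoothed percentile-rank
  method only.
* Grid-search candidates with two or three layers follow the funnel
  convention unless an explicit candidate list is supplied; the search is
  exhaustive only over the configured list.
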