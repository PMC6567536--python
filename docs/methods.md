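# Methods

## Population model

Each replication draws n = 1000 units. Predictors (x1, x2, x3) are
multivariate normal, mean 0, variance 1.15 each; x1 ⊥ x2, and x3 is
correlated ρ = 0.10 with x1. The continuous health outcome is

    y = 0.20·x1 + 0.30·x2 + 0.00·x3 + e,  e ~ N(0, 1),

giving Var(y) = (0.20² + 0.30²)·1.15 + 1 = 1.1495. The common variance
of 1.15 is what makes the residual variance of y exactly 1, which in
turn makes the ordered-probit latent metric coincide with the
population metric of y. Variances are enforced through the generator's
distribution parameters, not by rescaling drawn samples: 1.15 is a
population property, and per-sample rescaling would distort the
sampling variability that the coverage metric depends on.

Two choices here were genuinely open. The design only requires x3 to
be "weakly" related to one risk factor; we fix ρ(x1, x3) = 0.10 as the
default and expose it (`PopulationParams.rho_x3`), including 0 for
fully independent predictors. Nothing ties the two risk factors to each
other, so they are independent by default.

## Non-response model

The liability of non-response is

    L = b0 + b_non1·(x1 + x2 + x3) + b_non2·y + e_L,

with Var(e_L) chosen so that Var(L) = 1.15 in every condition. The
closed form substitutes y's generating equation: with
c = b_non1·1 + b_non2·b_pred, the explained variance is
c'Σ_x c + b_non2²·Var(e), which correctly accounts for the x–y
covariances (this algebra is verified against a brute-force Monte
Carlo variance at n = 10⁶ in the test suite). Combinations whose
explained variance reaches 1.15 are rejected up front.

Missingness is assigned by rank, not by fixed population cut-offs:

* **under-representation** — the ⌈n·(1 − response rate)⌉ units with the
  largest realized L are missing. At a 70% response rate this is the
  empirical analogue of the L > 0.52 SD rule (Φ(0.52) ≈ 0.70), at 50%
  of the L > mean rule.
* **extremes totally missing** — the top ⌈0.10·n⌉ realized outcome
  values are missing unconditionally (the empirical analogue of
  y > 1.28 SD), and the liability rule is then applied to the
  *remaining* units until the total missing count reaches
  ⌈n·(1 − response rate)⌉. Stronger dependencies make the two criteria
  overlap more, so the effective liability cut moves per sample — the
  calibrated cut is recorded on the returned sample (`l_cut`).

Rank-based assignment makes the achieved non-response rate exact in
every replication, which is how the study fixes its rates by
construction; a fixed population threshold would only hit them in
expectation. "Predicted" values of L and y are read as the *realized*
(generated) values: only that reading makes the nominal SD cut-offs
produce the stated 30%/50%/10% tail fractions, since the deterministic
linear predictor has far smaller variance than the total.

## Ordinalization

The observed scale cuts y at thresholds expressed in SD units of the
*theoretical* distribution of y (mean 0, SD √1.1495): −1/0/+1 for four
categories, −1/−0.5/+0.5/+1 for five, 0 for two. A value exactly at a
cut belongs to the lower category ("one SD or more below the mean" is
category 1); the event has probability zero and the convention exists
only for determinism. Anchoring thresholds to the theoretical rather
than post-missingness sample moments matters: after selective
non-response the sample moments are themselves distorted, and the
measurement instrument should not adapt to the selection. Missing
entries pass through ordinalization untouched.

## Estimators

All estimators target the association of the latent continuous
response with x1 and x2; the latent residual variance is fixed to 1,
so category probabilities are P(k) = Φ(θ_k − Xb) − Φ(θ_{k−1} − Xb)
with θ_0 = −∞, θ_K = +∞.

**Complete cases (CC).** Ordered probit (statsmodels `OrderedModel`,
probit link) on responders. L-BFGS with gradient tolerance 1e-8; on
non-convergence a BFGS restart from the first solution; failure marks
the replication non-converged and excludes it from aggregation (counts
are reported). A category empty after listwise deletion contributes no
threshold, i.e. is collapsed into its neighbour.

**FIML with auxiliary variable.** Missingness is confined to the
outcome, so the standard auxiliary-variable construction is a joint
model of the latent response and x3 given (x1, x2): y* probit-regressed
on x1 and x2; x3 linearly regressed on x1 and x2 with residual SD σ₃;
residual correlation r between the two equations. Responders contribute
the joint (category, x3) likelihood — analytically, the conditional
probit probability given e₃ times the marginal normal density of x3 —
and non-responders contribute the marginal density of x3 alone. The
likelihood is maximized by BFGS from CC-based starting values (a second
start with r = 0.3 if needed); standard errors come from the inverse
numerical Hessian. The exact likelihood used by the original
closed-source implementation of this estimator is not documented; the
joint model above is this package's own formulation, validated in the
tests against a numerical-integration oracle and by the FIML ≈ CC
pattern expected when the auxiliary carries little extra information.
Because FIML also uses x3, its estimates differ from CC by O(1/√n)
even with complete data; the "all estimators agree on complete data"
property is exact for MI and holds to ~0.02 for FIML.

**Multiple imputation (MI).** The ordinal outcome codes are imputed by
predictive mean matching — Bayesian draw of the linear-regression
parameters of y on (1, x1, x2, x3), donors selected among the 5
observed cases with closest predicted means (type-1 matching: drawn
parameters for missing cases, least-squares predictions for donors),
imputed value = the donor's observed code. Each completed data set is
analyzed by ordered probit and standardized; Rubin's rules pool on the
standardized metric (mean estimate; within + (1 + 1/m)·between
variance). Default m = 50 imputations, donor pool 5. PMM is implemented
in-package; imputation runs that fail to converge are dropped with a
logged count, and more than 20% dropped marks the pooled result
non-converged. With zero missing values no imputation is performed and
the CC result is returned unchanged.

**Linear regression follow-up.** OLS of the untransformed continuous
outcome on x1 and x2 among responders, reported unstandardized (already
on the population metric).

**Standardization.** bs_j = b_j·SD(x_j)/SD(u*), with
SD(u*) = √(b'Sb + 1) using all analysis predictors jointly and S the
sample covariance of the rows entering the fit (complete cases for CC;
all rows for FIML and MI, whose likelihood/imputation uses all rows).
Standard errors are multiplied by the same per-coefficient factor — a
delta-method approximation that ignores the sampling variability of
the scale factor — and 95% CIs are Wald, bs ± 1.96·SE. The
approximation slightly understates the SE; empirically coverage in
unbiased conditions stays within 93–97%.

## Metrics

Relative bias = 100·(true − mean estimate)/true, computed on the mean
estimate across converged replications (by linearity identical to the
mean of per-replication biases); attenuation of a positive coefficient
is positive. Coverage = percentage of converged replications whose
Wald 95% CI contains the truth. Potential for preventing bias
= 100·(R1 − R2)/R1 where R1/R2 are the relative biases with extremes
totally missing / merely under-represented; undefined when R1 = 0
(reported as not applicable, never as a number), and the boundary
identities (R2 = 0 → 100, R2 = R1 → 0) are returned exactly. Tables
round estimates and SEs to 2 decimals and coverage to integers.

## Scenario grid and reproducibility

The main grid crosses dependency pairs
(b_non1, b_non2) ∈ {(0.3,0), (0.1,0.1), (0.3,0.1), (0,0.3), (0.1,0.3),
(0.3,0.3)} with response rates {0.70, 0.50} and both extreme-scorer
regimes on the 4-category scale; follow-up conditions re-run the 50%
grid with 5 categories, 2 categories, and the continuous outcome.
Replication r of a scenario seeds a `SeedSequence` with
(base seed, CRC-32 of the scenario configuration, r) and spawns
independent child streams for sampling, liability noise and
imputation, so results are identical across runs and worker counts and
no replication's stream depends on execution order.

Default sizes are the study conditions: n = 1000 per sample, 500
replications per scenario, 50 imputations. The test suite and the
acceptance script run the single-estimator checks at the full 500
replications; the three-estimator agreement check runs at 100
replications with 10 imputations, a deliberate desk-scale setting whose
Monte Carlo error (~0.003 on a mean estimate) is well inside the 0.015
agreement margin being tested.

## What the generator does and does not emulate

It emulates: a continuous latent health trait measured on a coarse
ordinal scale; non-response driven by a smooth latent liability related
to risk factors and outcome; exact-by-design response rates; and the
presence/absence contrast for extreme scorers. It does not emulate:
non-normal or skewed traits, measurement error in predictors,
missingness in predictors, longitudinal wave-by-wave attrition,
item-level missingness, or informative cluster structure. Passing tests
therefore speak to bias mechanics under a clean liability-threshold
MNAR model, not to every real survey's missingness process.

## Known limitations

* The FIML likelihood is this package's formulation of the
  auxiliary-variable joint model, not a reproduction of any specific
  software's internals.
* SEs of standardized estimates use the fixed-scale-factor
  approximation; coverage in heavily biased conditions is driven by
  bias, but in borderline conditions the approximation can shave a
  point or two off coverage.
* Relative bias uses the mean (not median) of replication estimates.
* The x3–x1 correlation (0.10) is a default for an unquantified
  "weak" association; sensitivity runs should vary `rho_x3`.
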