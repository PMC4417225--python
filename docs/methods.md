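# Methods

This note documents the statistical models implemented in `longexpo`, the
assumptions they make, the synthetic-cohort generator used to exercise them,
and the numerical choices a maintainer would want to know about.

## Data model

A cohort is long-format: one row per subject-visit with a positive exposure
(analyzed on the natural-log scale, the usual treatment of right-skewed
biomarker concentrations), observation time in gestational days (strictly
increasing within subject), time-varying covariates (urine specific gravity
as a dilution indicator, a binary time-of-day flag), and subject-level
baseline covariates plus a binary outcome. A missing exposure at a visit is
an absent record; no imputation is performed anywhere — each method defines
its own subject-inclusion rule, which is why the analysis `n` differs across
methods on unbalanced data.

Internally time is kept in gestational days; models center time at the
cohort mean and scale to weeks so design matrices stay well conditioned;
summaries report weeks.

Reproducibility diagnostics: the ICC is the between-subject variance share
from an intercept-only random-intercept REML model, with a subject-level
nonparametric bootstrap CI (the closed-form CI depends on balance
assumptions the data do not satisfy; B = 500 by default, seeded). Pairwise
visit correlations use pairwise-complete subjects.

## The nine outcome models

**1. Multiple logistic regression.** All visit exposures enter one logistic
model simultaneously; only complete cases can be used, and collinearity of
the repeated measures inflates the coefficient covariance. The Bayesian
variant replaces the MLE with a MAP estimate under a mean-zero Gaussian
prior on the visit-coefficient block with covariance τ²R(ρ), R an AR(1)
correlation over visit order (temporally adjacent coefficients shrink
together; intercept and covariates unpenalized). τ² and ρ can be fixed or
chosen on a small grid (τ² ∈ {0.01, 0.1, 1, 10}, ρ ∈ {0, 0.3, 0.6, 0.9}) by
the Laplace-approximate marginal likelihood. The posterior covariance is the
Laplace approximation at the mode. The effect is ridge-like attenuation of
the correlated coefficients toward zero.

**2. Parallel cross-sectional models.** One logistic fit per visit on the
subjects observed at that visit; optional Bonferroni adjustment (×n, capped
at 1). The joint version is a working-independence GEE over subject-visit
pseudo-observations, fully stratified by visit (visit-specific intercepts,
exposure coefficients and covariate effects), so the point estimates
coincide exactly with the separate per-visit MLEs; the subject-clustered
sandwich covariance ties the visits together and yields a Wald test of
H₀: β₁ = … = β_n with the contrast of successive differences, df = n − 1.
Full stratification of *all* covariates is what makes the estimate identity
exact; a shared-covariate parameterization would only approximate it.

**3. Mean summary.** Logistic on the subject mean of ln exposure over the
available visits — equivalently the ln geometric mean of the raw values.
Time-varying covariates are averaged per subject (a binary becomes the
subject's proportion). Every subject with ≥ 1 visit is used: the permissive
inclusion rule, with `n_used` always reported.

**4. Max summary.** Logistic on the subject maximum of ln exposure, with
the time-varying covariates of the visit attaining the maximum; ties break
to the earliest visit (a deterministic, documented rule). Matched to acute
effect mechanisms; under outcome-differential dropout it is *biased even
under the null* — see "Known limitations".

**5. Two-stage mixed model.** Stage 1 is a REML linear mixed model of ln
exposure on centered time (weeks) with subject random intercept and slope
(bivariate normal) plus time-varying covariates as fixed effects. BLUPs are
the conditional means given the REML variance components. The `auto` slope
policy refits intercept-only when the slope is redundant: |random-effect
correlation| > 0.95 (configurable), a boundary variance estimate, or a REML
improvement below 6.68 — the 2.5% critical value of the 0.5·χ²(1)+0.5·χ²(2)
boundary mixture for testing the slope variance/covariance against zero.
The conservative level is deliberate (keep the slope only on strong
evidence; the finite-sample null distribution of the REML improvement runs
slightly heavy). Stage 2 is a logistic model of the outcome on the BLUPs
plus baseline covariates; alternatively, the (intercept, slope) BLUPs are
z-standardized (their raw scales differ by orders of magnitude), k-means
clustered (20 seeded restarts), relabeled by ascending mean intercept, and
the cluster indicators enter stage 2. Stage-2 standard errors treat the
BLUPs as known; the unpropagated stage-1 uncertainty can understate stage-2
uncertainty, and the simulation harness measures rather than hides this.

**6. Trajectory-contrast GAMM.** The reverse-temporal model treats ln
exposure as the response: X_ij = b₀ᵢ + f₁(t) + Yᵢ·f₂(t) + Z'η + ε, with
subject random intercept and penalized cubic-spline smooths. It contrasts
the exposure trajectories of the two outcome groups; risk is never
estimated from it and its output is descriptive. The difference term f₂ is
constant (unpenalized group offset) + penalized linear + penalized smooth
deviation, so its effective degrees of freedom read 1 for a pure level
shift, 2 for a linear divergence, and more for curvature. Everything is one
Gaussian mixed model: smooth deviations and subject intercepts are random
blocks whose variance ratios are estimated by REML (profiled likelihood;
the subject block of the normal equations is diagonal, so a Schur
complement reduces each criterion evaluation to small dense algebra).
Reported: fitted group curves with pointwise bands, the difference curve,
its EDF, a Wald test of the (penalized) linear difference slope, and an
approximate "interaction" test — a Gaussian profile-likelihood LRT removing
all outcome-dependent terms with df equal to the rounded difference EDF,
labeled approximate in the output.

**7. Gaussian mixture clustering.** Complete-case exposure vectors are fit
with K-component full-covariance Gaussian mixtures (EM, seeded k-means
initialization, 10 restarts, ridge ε·tr(S)/d on the covariances against
singularity), K = 1…k_max selected by BIC in the "larger is better"
convention 2·logL − m·log N — stated explicitly because both sign
conventions circulate. Cluster labels are ordered by ascending overall mean
so odds ratios have a stable reference.

**8. Functional clustering.** Each subject's (time, value) points are
summarized by a least-squares line (a constant for single-visit subjects) —
with at most four irregular points per subject a richer basis is not
identifiable — evaluated on a common grid (default 20 points) and k-means
clustered (20 seeded restarts); the centroids approximate principal points
of the curve distribution. Balance is not required. Optionally the curves
are built from covariate-residualized exposures (pooled least-squares
residualization), for the case where raw-curve clusters merely reflect a
covariate; a per-covariate dependence screen (ANOVA / χ²) is attached to
the cluster model as a diagnostic.

**Cluster→outcome association (7, 8).** A χ² independence test on the K×2
cluster-by-outcome table (df = K − 1, uncorrected), with an expected-count
warning and a Fisher-exact fallback for degenerate 2×2 tables, plus a
logistic model on K − 1 cluster indicators with baseline covariates. Any
cluster below 5% of subjects triggers an instability note.

**9. Functional logistic regression.** Sparse FPCA of the ln-exposure
process: the mean is a penalized B-spline smooth of the pooled points (GCV
over a log-spaced λ grid); the covariance surface is a tensor-product
B-spline smooth of raw residual cross-products over off-diagonal pairs only
(the diagonal is contaminated by measurement error); the noise variance σ²
is the average, over the central half of the time range, of the smoothed
diagonal minus the surface diagonal, floored at zero; eigenfunctions and
eigenvalues come from the trapezoid-weighted eigendecomposition of the
discretized surface (negative eigenvalues truncated with a warning); and
per-subject scores are conditional expectations under the Gaussian working
model, ξ̂ᵢₗ = λₗ Φᵢₗᵀ Σᵢ⁻¹ (Xᵢ − μᵢ) with Σᵢ = ΦΛΦᵀ + σ²I on the subject's
own time points — the standard estimator for sparse, irregular designs.
The outcome model is a logistic regression on the leading L scores plus
baseline covariates with an L-df LRT against the covariate-only model; this
two-step version is implemented and labeled as such (a joint-likelihood
variant is not attempted). β(t) = Σ βₗφₗ(t) is returned with plug-in bands
flagged as ignoring FPCA estimation uncertainty. Model selection offers a
modified BIC (pooled marginal Gaussian log-likelihood minus ½·m·log of the
observation count, m = n_basis·(1+L) + L + 1) and an approximate
leave-one-curve-out CV that refits on ten subject folds rather than N
(exact LOCV is O(N) refits); the fold count is configurable and the
approximation is documented in the selection output. Defaults: grid 51
points, basis grid {5, 7, 9, 11}, L grid {1, 2, 3}.

## Synthetic cohorts

The generator emulates the structure of a four-visit pregnancy biomarker
study: 480 subjects; visit windows with medians 9.79 / 17.9 / 26.0 / 35.1
weeks and the published ranges, times drawn uniformly within each window
(the least-informative choice consistent with a median and range) and
sorted; ln exposure from a random-intercept(/slope) Gaussian model whose
intercept share of total variance equals the ICC target (reference settings
0.30 and 0.57); specific gravity ~ N(1.015, 0.005²) truncated to
[1.000, 1.040] and time-of-day ~ Bernoulli(0.5) entering the exposure model
centered (physiologic defaults, all configurable); a baseline log-odds
giving ≈ 27% cases (130/482); and loss of the final visit with
outcome-dependent probability (defaults 0.60 for cases, 0.07 for controls,
chosen so overall visit-4 availability matches the emulated study's
380/482) applied *after* the outcome is drawn. The outcome is prospective
logistic — odds ratios are invariant to outcome-dependent sampling, so this
also represents a nested case-control design analyzed with unweighted
logistic models. The preset's population time trend is zero and its random
slope SD is 0.01 ln-units/week: a nonzero trend combined with differential
dropout would bias even the mean-summary null test, and a larger slope SD
measurably erodes the exchangeable-correlation ≈ ICC identity; trend
scenarios set both explicitly.

Effect mechanisms add one term to the outcome's linear predictor:
`mean` (effect × subject mean ln exposure over the scheduled visits),
`window` (exposure at one visit), `acute` (subject maximum), `slope`
(effect × the latent random slope, in log-odds per ln-unit/week), or
nothing (`null`). The truth record carries the latent random effects, the
effect feature and the linear predictor for recovery studies. Because
slopes are latent with small SD, slope scenarios need effect sizes scaled
to that SD; the harness's trend scenario uses slope SD 0.05 with effect 25
(latent effect SD 1.25 on the log-odds scale).

What the generator does **not** emulate: limit-of-detection censoring,
covariate-outcome confounding, non-Gaussian exposure shapes beyond
log-normality, missingness at interior visits, and multi-pollutant
mixtures. Passing tests therefore demonstrate correct behavior under a
log-normal exchangeable exposure process with MAR final-visit dropout, not
robustness to those features.

## Operating characteristics

The harness runs each method's headline test over seeded replications of a
scenario grid: any-visit Bonferroni Wald (method 1), GEE equality and
per-visit tests (2), the exposure Wald (3, 4), the BLUP Walds (5), the
approximate interaction test (6), the cluster χ² with K pinned at 2 (7, 8 —
a BIC-selected K of 1 would leave no test, and an arbitrary K = 2 split of
homogeneous data remains independent of the outcome, so the χ² keeps its
level), and the L-df LRT (9). Rejection rates come with Monte Carlo
standard errors; bias and RMSE are reported where the scenario's effect
size is the direct target of the reported coefficient (the mean mechanism);
failed replicates are counted, never silently dropped; per-replicate
records stream to disk.

Type-I calibration is run under a null with the study's visit-4 missingness
made non-differential (equal dropout 0.21 for cases and controls): with
*differential* dropout the max-summary statistic is biased under the null —
cases take a maximum over three visits, controls over four, so the
case-control contrast is nonzero with no exposure effect. That inflation
(~0.1–0.2 at N = 480 at the default dropout rates) is itself measured and
reported by the acceptance script as `type1_max_summary_differential_dropout`.
Problem sizes: 500 replicates at N = 480 for the calibration stream (200
for the two smoothing-heavy methods, the trajectory GAMM and the functional
LRT), 200 replicates at N = 2000 for power orderings, and N = 4000 for
mean-effect recovery.

## Numerical choices

- Logistic MLE by IRLS; convergence on |Δdeviance| < 1e-8, cap 100
  iterations; covariance from the observed information. Suspected
  separation (a standardized coefficient beyond 10, configurable) is
  flagged with `converged=False` rather than raised.
- Mixed-model REML profiles out the residual variance and the fixed
  effects; the 2×2 random-effect covariance uses a log-Cholesky
  parameterization (entries clipped at ±9 — variance ratios beyond ~e^18
  leave the GLS fixed effects numerically unidentified), Nelder-Mead with
  up to 5 seeded restarts and early stop when two starts agree. All
  per-subject algebra is reduced to batched 2×2 operations via the Woodbury
  and push-through identities; BLUPs use the cancellation-free form
  (G⁻¹ + ZᵢᵀZᵢ)⁻¹ Zᵢᵀrᵢ.
- GAMM smoothing parameters: REML over log variance ratios with a boundary
  rule that drops a component unless it improves the criterion beyond 2.71
  (the 5% point of the 0.5·χ²(0)+0.5·χ²(1) mixture); this also rescues the
  simplex from the flat likelihood tail. The spline penalty is the
  integrated squared second derivative, whose null space is exactly
  {1, t} — a coefficient-difference penalty on non-uniform knots leaks
  level/trend into the "smooth deviation" block and distorts the EDF.
- Mixture covariances carry a relative ridge 1e-6·tr(S)/d; duplicated
  visits therefore degrade gracefully.
- FPCA truncates negative surface eigenvalues to zero (count reported),
  floors σ² at 1e-8 in score computation, and fixes eigenfunction signs by
  positive integral.
- k-means everywhere: 20 restarts (10 inside the mixture initializer),
  seeded; cluster labels ordered by ascending mean level.

## Known limitations

- Stage-1 uncertainty (BLUPs, cluster assignments, FPC scores) is not
  propagated into stage-2 standard errors for methods 5, 7, 8; method 9's
  β(t) bands are plug-in. Coverage can fall below nominal when stage-1
  noise is material.
- The max-summary model is not a valid null test under outcome-dependent
  dropout (measured and reported, see above); no inverse-probability
  weighting is implemented beyond the sensitivity hooks.
- The GAMM interaction test's df (rounded EDF) and Gaussian profile LRT are
  approximations; its p-values should be read as indicative.
- With ≤ 4 visits per subject, functional methods (6, 8, 9) identify at
  most low-dimensional structure; the per-subject line representation and
  L ≤ 3 defaults reflect that.
- Exposure-response nonlinearity is available only through the
  exposure-transform hook on methods 1-4 (default identity); full smooth
  exposure-response models are out of scope.
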