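# Methods

This note documents the statistical machinery in `pfactor`: the models, the
estimators, the synthetic-cohort generator and its defaults, the numerical
choices, and the limits of what the simulations demonstrate.

## Measurement model

The 12 parent-rated symptom scales (depression 12 items, generalized anxiety
7, separation anxiety 10, social anxiety 6, specific phobia 7, irritability
3, headstrong 4, hurtful 2, conduct 7, hyperactivity/impulsivity 9,
inattention 9, social-communication 12; items scored 0–2) are modelled by an
orthogonal bifactor confirmatory factor model. Every scale loads on the
general factor P; the anxiety/mood scales additionally load on an emotional
factor E, the oppositional scales on a behavioural factor B, and the
ADHD/ASD scales on a neurodevelopmental factor N. All factor variances are
fixed to 1 and all factor covariances to 0, which identifies the model and
makes loadings standardized when the input scores are standardized (the
default in `BifactorModel.from_scores`).

Conduct problems are given a general-factor loading and no specific loading
by default. The placement of this single loading is genuinely ambiguous in
the reference solution the defaults emulate; `BifactorSpec.default(
conduct_on_specific=True)` places it on the behavioural factor instead
(model df 42 rather than 43).

**Estimation.** Free parameters (23 or 24 loadings, 12 unique variances)
minimise the ML discrepancy

    F_ML = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p,   Sigma = Lambda Lambda' + Theta

by L-BFGS-B with analytic gradients (2(G Lambda) for loadings and diag(G)
for uniquenesses, G = Sigma^-1 (Sigma - S) Sigma^-1). Unique variances are
log-parameterised to stay positive; solutions with theta < 1e-4 are flagged
Heywood-adjacent. Start values are 0.4 (general loadings), 0.2 (specific),
0.6 (uniquenesses), with two additional ±0.1-jittered starts as a guard
against local minima; the best of the three is kept. Convergence requires
gradient norm < 1e-6 (optimizer ftol 1e-15). Sign convention: each factor's
largest-magnitude loading is made positive, ties broken toward a positive
loading sum. The sample covariance uses listwise-complete cases
(full-information ML is out of scope); chi² = (n−1)·F_ML with no
non-normality scaling correction — robustness to non-normality is carried
by the sandwich standard errors instead, so fit indices approximate rather
than replicate software that rescales chi².

**Fit indices.** With baseline = independence model (free variances only,
F_b = Σ ln S_ii − ln|S|, df_b = p(p−1)/2):

    CFI   = 1 − max(chi2_m − df_m, 0) / max(chi2_b − df_b, chi2_m − df_m, 0)
    TLI   = ((chi2_b/df_b) − (chi2_m/df_m)) / ((chi2_b/df_b) − 1)
    RMSEA = sqrt(max(chi2_m − df_m, 0) / (df_m (n−1)))

Conventional good-fit cutoffs: CFI > 0.95, TLI > 0.95, RMSEA < 0.06.

**Standard errors.** Naive SEs come from the inverse observed information
(numerically differentiated mean casewise score). Robust SEs use the
sandwich A⁻¹BA⁻¹/n with B the empirical covariance of analytic casewise
scores. Under multivariate normality the two agree (tested, ratio within
[0.9, 1.1] at n = 20,000). Excess kurtosis in the *unique* errors inflates
the uniqueness-parameter SEs (the fourth-moment terms enter those scores);
excess kurtosis in the *factors* inflates loading SEs. Both directions are
tested, and loading SEs agree with a case-resampling bootstrap within 15%
under t(3) unique noise.

**Factor scores.** Regression-method scores Λ'Σ⁻¹(x − x̄) (factor
covariance identity) are the user-facing scores; Bartlett scores
(Λ'Θ⁻¹Λ)⁻¹Λ'Θ⁻¹(x − x̄) are used inside the association estimator because
they are conditionally unbiased for the factors (WΛ = I). Persons with any
missing scale get missing scores.

## Omega reliability

On the standardized solution, with unit-weight composites:

    omega    = [(Σλ_g)² + Σ_s (Σλ_s)²] / [(Σλ_g)² + Σ_s (Σλ_s)² + Σθ]
    omega_H  =  (Σλ_g)² / same denominator

and per specific factor s, restricting all sums to s's items,

    omega_S  = [(Σλ_g)² + (Σλ_s)²] / [(Σλ_g)² + (Σλ_s)² + Σθ]
    omega_HS =  (Σλ_s)² / same subscale denominator.

omega_H isolates the general factor's share of reliable composite variance;
omega_HS is the subscale analogue after removing the general factor. All
intermediate sums are reported for audit. Inadmissible solutions (θ ≤ 0)
are rejected. The implementation is verified against an independent
decomposition that sums covariance-matrix blocks instead of squaring
loading sums, on 100 random admissible matrices, to 1e-10.

## Two-step association

Step 1 fits the measurement model and freezes Λ, Θ. Step 2 estimates
standardized effects of the four PRS (entered simultaneously) and sex on
each factor with measurement fixed. Because the factor variances were fixed
at 1 in step 1, the structural ML estimator reduces exactly to (weighted)
least squares of Bartlett factor scores on the predictors: the GLS weight
(Λ'Σ⁻¹Λ)⁻¹Λ'Σ⁻¹ equals the Bartlett weight (Λ'Θ⁻¹Λ)⁻¹Λ'Θ⁻¹ by the Woodbury
identity, and Bartlett scores are conditionally unbiased given the
predictors. This is the default mode (`fixed_measurement`). A plain OLS on
regression-method factor scores is provided as `factor_score_ols` for
cross-checks; it is attenuation-prone (regression scores shrink toward
zero) and tested to be so.

Continuous predictors are Z-standardized internally (weighted moments when
case weights are present); binary predictors such as sex stay as coded, so
the sex beta is the female−male contrast on the factor scale. Sex is an
adjustment covariate by default (toggleable) since the reference analysis
does not state it. Two-sided p-values come from sandwich-SE Wald statistics
against the normal reference. Per-factor R² is the explained latent
variance β'Ĉov(z)β (factor variance ≡ 1), which by the normal equations
equals Σ_j β_multi,j · β_uni,j — an identity the tests check numerically.
Collinear predictor sets (condition number > 1e8) are rejected naming the
offending pair. Univariable fits re-enter one PRS at a time with the same
covariates.

## PRS engine

Harmonization orients discovery effects to the panel's alternate allele
(match keeps, swap negates, strand-ambiguous A/T and C/G pairs dropped by
default, mismatches dropped; every category counted and logged). Clumping
is the standard greedy pass: smallest-p unclaimed SNP becomes an index,
unclaimed SNPs within 250 kb with dosage r² ≥ 0.1 are claimed; ties on p
break by (chromosome, position). Scoring includes retained SNPs with
p < threshold (strict; threshold 1.0 means all), orients each weight to its
risk allele (negate and use 2−dosage when the effect is negative), and
divides by 2 × the per-person count of non-missing included SNPs, so people
with missing dosages remain comparable; scores are then Z-standardized.
The divisor and the clumping parameters are conventional defaults, not
reference-prescribed; Z-standardization makes multiplicative constants
irrelevant for association. The primary threshold is p < 0.05 with a sweep
over {0.001, 0.01, 0.05, 0.1, 0.5, 1.0}.

## Synthetic cohort generator

The generator emulates a birth cohort of order 10⁴ children with the
statistical structure the analysis assumes; every stage stores its
generating truth for oracle tests.

- **Genotypes.** Hard dosages as two haplotypes under Hardy–Weinberg at a
  per-block MAF ~ U(0.05, 0.5). LD is block-wise (50 SNPs per block): each
  haplotype allele copies the block's anchor with probability r, where r²
  ~ U(0, 0.95), giving corr r with the anchor and r² between non-anchor
  pairs; the block r is stored. 5% of variants get strand-ambiguous allele
  pairs (a post-QC-like rate) to exercise the harmonization drop.
- **Summary statistics.** True per-SNP effects at a shared causal set
  (default 40 SNPs, spread at most one per LD block so clumping retains
  distinct signals), drawn jointly across the four discovery traits with a
  configurable correlation matrix (default identity; real discovery traits
  correlate ~0.3–0.9) and scaled so each true polygenic value has variance
  0.2. Observed effects add N(0, SE²) noise with SE = 1/sqrt(gwas_n ·
  2·maf·(1−maf)); p-values are two-sided normal. SE scales as 1/sqrt(gwas_n)
  (tested); gwas_n = inf gives noiseless statistics.
- **Phenotypes.** Latent factors = factor_betas × [standardized true
  polygenic values, sex] + independent residual scaled so each factor has
  unit variance. Default structural effects are the package's reference
  values (e.g. ADHD→P 0.087, female sex→P −0.106). Scale liabilities =
  Λf + unique error with the reference loading matrix (unit variance by
  construction). Each scale's m ordinal items are generated from the scale
  liability with item reliability 0.7 (a realistic parent-report value) and
  cut at the 70th and 90th liability percentiles — right-skewed, as symptom
  data are. The distributional form of real scale scores is unknown; this
  liability-threshold construction is a stand-in.
- **Missingness and availability.** Items are blanked independently at 2%
  by default. Genotype availability follows a logistic model on latent P
  (slope −0.5) or on the observed standardized mean symptom score, with the
  intercept calibrated by root-finding so expected availability hits the
  target (default 0.68).
- **Families.** 1% of persons become the second-born of another person's
  family, solely to exercise the oldest-sibling filter.

Ordinalization + proration attenuate the scale-score loadings relative to
the generating liabilities (the fitted general loadings are ≈ 0.85–0.9 of
the generating values), but the latent factors themselves keep unit scale,
so structural betas are recovered with only a small residual bias
(≈ −0.006 on a beta of 0.087 at n = 50,000 — within the recovery
tolerances). What passing recovery tests show is that the *pipeline*
estimates the *generating* structure correctly; they do not show that real
symptom data satisfy the linear factor model, nor do they validate
imputation quality, population stratification handling, or discovery-GWAS
internals, none of which are simulated.

## Scale scoring rules

Prorated score = mean of answered items × item count, valid only when the
missing fraction is strictly below 30% (a 12-item scale tolerates 3 missing
items; 4 fails; a 10-item scale with exactly 3 missing — 30% — is scored
missing). On complete data the prorated score equals the raw sum. Scores
are Z-standardized before the covariance is computed, so the reported
loadings are on the standardized scale. Families contribute the lowest
birth order; duplicate (family, birth-order) pairs are rejected.

## IPW sensitivity

Availability is modelled by logistic regression (IRLS via statsmodels GLM)
on fully observed predictors — by default sex plus the 12 observed scale
scores, the information a cohort holds before genotyping. Weights for
available persons are (marginal rate)/p̂ (stabilized; unstabilized 1/p̂
optional), fitted probabilities floored at 1e-6 with a count of floored
cases, and trimmed at the 99th percentile by default. Trimming buys
variance at the price of a small residual bias when selection is strong —
measured directly in the bias-reduction experiment below. The association
stage is re-run with the weights entering the standardization, the normal
equations, and the sandwich meat (probability-weight convention: the meat
uses w²e²; integer weights therefore reproduce point estimates, not SEs, of
a physically duplicated data set). Effective sample size (Σw)²/Σw² below 50
triggers a warning.

## Replicated studies (`pfactor.experiments`)

Problem sizes are package choices that keep each study's Monte-Carlo error
well below the property being demonstrated.

- **Null calibration:** measurement fixed once on a 20,000-person null
  cohort; 2,000 replicates of n = 400 with all structural effects zero; all
  16 factor × PRS Wald p-values pooled. Empirical type-I error at α = 0.05
  lands within 0.05 ± 0.015.
- **Attenuation:** two scores correlated 0.5, true effect 0.2 through the
  first only, n = 50,000. Closed-form targets: multivariable beta₂ = 0,
  univariable beta₂ = 0.1.
- **IPW bias reduction:** one true PRS effect (0.1) on P; availability
  logistic on the observed symptom composite with slope −1.5 and target
  0.68; n = 8,000 per replicate, 200 replicates. The operating point was
  chosen so the selection bias (unweighted ≈ −0.037) dominates paired
  replicate noise — a stronger gradient and larger n make the check harder
  for a broken IPW, not easier. The weighted estimate is closer to the
  full-data estimate in ≈ 9 of 10 replicates; the residual weighted bias
  (≈ −0.01) is the cost of default weight trimming.

## Known limitations

- Complete-case covariance and factor scores; no full-information ML, no
  multiple imputation, no categorical-indicator (WLSMV-style) estimation.
- chi² is unscaled ML; fit indices from heavily non-normal data inherit
  that.
- The LD model is equicorrelated-within-block with a single block MAF; no
  LD decay with distance, no reference panel distinct from the target.
- No population stratification, X chromosome, or imputation uncertainty.
- Omega values depend on the (standardized) solution; no confidence
  intervals are provided.
- Ages are independent runs with different configs; no longitudinal
  measurement-invariance modelling.
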