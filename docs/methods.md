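# Methods

This note records the generative models, estimators, numerical choices
and known limitations of `wsplab`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Cohort generator

Individuals carry sex (0 = female, 1 = male), age, per-variant allele
dosages, an unmeasured environmental confounder `E ~ N(0,1)`, a latent
assortment score `A`, ten ancestry covariates `pc1..pc10`, and one or
more phenotypes. The phenotype is additive:

    P = Σ_j β_j g_j + c·E + a·Age + s·Sex + offset·subpop + ε,
    ε ~ N(0, noise_sd²).

Choices and rationale:

- **Dosages are exact {0, 1, 2} counts** — two Bernoulli(f) draws per
  variant — so within-pair genotype differences live in {−2, …, 2} and
  difference arithmetic is exact. No linkage disequilibrium, dominance,
  or X-chromosome model.
- **Age** is Uniform(40, 70) years (configurable), a middle-aged cohort;
  only age *differences* enter the analysis models, so the marginal
  shape is largely immaterial.
- **Stratification** uses exactly two equiprobable subpopulations.
  Per-variant frequencies are `f ± d·f(1−f)` (divergence parameter
  `d ∈ [0,1]`), clipped to (0.01, 0.99); subpopulation 1 carries both
  the higher frequencies and the phenotype offset, so every divergent
  variant is confounded upward. `pc1` is the centred membership
  indicator plus `N(0, ancestry_noise_sd²)` noise; `pc2..pc10` are pure
  noise, mirroring the convention of adjusting for ten principal
  components of which few carry structure.
- **Assortment score** `A` is a weighted sum of standardised cohort
  columns (any of `E`, `age`, a phenotype, an ancestry covariate) plus
  `N(0, assortment_noise_sd²)` noise. Standardising makes weights
  comparable across columns with different scales.
- **Shared spousal environment** is applied after pairing: one
  `N(0, shared_env_sd²)` draw added identically to both members. The
  cancellation from within-pair differences is structural; numerically,
  only IEEE addition round-off (≲1 ulp of the shifted values, asserted
  below 1e−12) distinguishes differences before and after.
- **Siblings** are generated by explicit Mendelian segregation: two
  parental allele pairs per family and variant, each offspring
  independently inheriting one allele per parent. This yields the
  classical sibling dosage correlation of 1/2 at any allele frequency.
  Families share a subpopulation and a family-level environment
  component of SD `shared_env_sd`.
- **Binary phenotypes** are liability-threshold dichotomisations: cases
  are the top `prevalence` fraction of a continuous liability. The
  threshold is the empirical quantile, so realised prevalence is exact
  by construction. The 10% default for the negative control's disease
  outcome is a design choice; nothing in the modelled disease pins it.
- **Randomness**: a single root seed with named child streams
  (SHA-256-hashed labels feeding a `SeedSequence`), so each stage can be
  re-run in isolation and identical (parameters, n, seed) yield
  byte-identical output files.

## Pairing

`rank_match_pairs` sorts each sex descending on the score with stable
tie-breaking by input order and matches by rank; the male is always the
index member, which makes "sex of the index individual" well defined
(and constant, hence pruned, in male-indexed linear spouse models).
Unequal sex counts are a hard error — silent trimming would bias the
matched sample.

Quantile matching on `A` makes the matched scores nearly equal within a
pair, so for a trait `V` with `Corr(V, A) = C` the induced spousal
correlation converges to `C²` (the correlation of two conditionally
independent draws given the common score). The Model A driver therefore
reports both the assortment parameter `C` and the *measured* spousal
confounder correlation per grid point, and downstream claims are stated
against the measured correlation.

Random-pair nulls permute the female partners uniformly against the
fixed males, 100 replicates by default; a random pair may coincide with
a true couple (no derangement is enforced, matching the plain meaning of
random re-pairing). Replicates are exchangeable by construction.

## Difference regressions

`compute_pair_differences` emits index-minus-partner differences for the
outcome, each predictor and each covariate, plus the index member's sex;
complete-pair analysis only, with logged attrition (no imputation).

**Intercept policy.** Pure-difference linear designs — every regressor
antisymmetric under pair-order reversal — are fit *without* an
intercept: the population intercept is zero by symmetry, and omitting it
makes the fitted slope exactly invariant to reversing the order of any
subset of pairs. Designs containing `index_sex` (which swaps rather than
negates) and all logistic fits include an intercept. The practical
difference from always including one is O(1/n) on difference data.

**Covariates.** Spouse models use the index member's sex and the age
difference; sibling models substitute the sex difference for index sex
(both members' sexes vary); random-pair reference models optionally add
the ten ancestry-covariate differences. Constant columns (index sex in
male-indexed linear spouse models) are pruned with a logged note rather
than erroring. Classical (non-robust) OLS standard errors: pair
differences are i.i.d. across pairs under the generator, so
heteroskedasticity-robust machinery would add noise, not protection.

**Binary outcomes.** Pairs are reoriented so the outcome difference is 0
or 1. Discordant pairs index the case. Concordant pairs (case–case,
control–control) are *retained* with outcome 0 and modelled by
unconditional logistic regression — deliberately not the discordant-only
conditional-logistic convention of matched case–control studies; the
within-pair "difference" here is an outcome, not a matching stratum.
Concordant pairs are put into a canonical orientation keyed to an
order-invariant hash of the two ids. This serves two purposes: the
oriented table (hence every estimate) is identical whichever member was
initially the index, and when the input pairing is uniformly
male-indexed it prevents a structural quasi-separation in which
`index_sex = 0` occurs only among discordant pairs, which would make the
logistic MLE diverge. Fit failures from genuine separation are reported
as errors naming the predictor, never silently.

**Random-pair summarisation** takes the per-variant median effect and
median SE across replicates (robust to the occasional unstable
replicate; means would be dominated by tails in small samples).

## IVW and shrinkage

    β_IVW = Σ w_j β_j / SE_j²  ÷  Σ w_j² / SE_j²,   SE_IVW = (Σ w_j²/SE_j²)^(−1/2)

with `w_j` the discovery effect size and `SE_j` the *within-pair model's*
per-variant SE (discovery SEs are not used). This equals the
no-intercept weighted least-squares slope of β on w with weights 1/SE²
— the effect of the discovery polygenic score on the phenotype in that
model — verified to 1e−10 against `statsmodels` WLS.

Shrinkage is `100·(1 − β_comparison/β_reference)`; positive values mean
the comparison (within-pair) estimate is attenuated toward zero. The SE
is the first-order delta method on the ratio with zero covariance
assumed between the two models' estimators, and the 95% CI is normal
(± 1.96 SE). Order of approximation and CI form are package choices; the
delta SE matches a 10⁴-draw parametric bootstrap within 5% whenever the
reference satisfies |β| > 10 SE, and below that threshold a warning is
raised (the ratio distribution grows heavy tails; the interval is then
unreliable but not silently wrong). An exactly zero reference β is an
error. Heterogeneity between two shrinkage estimates reuses the normal
difference-of-two-means test on the shrinkage scale; all p-values are
two-sided.

Known limitation: when many variants are estimated marginally against
the *same* phenotype vector, the per-variant estimates are positively
correlated and the IVW information sum overstates precision — measured
as ~93% coverage of a nominal 95% CI in a shared-sample harness. This is
a property of the IVW formulas as printed (and as used in the field),
not of this implementation; the coverage calibration harness therefore
estimates each variant from its own independent sample, the sampling
model the formulas assume.

## Experiment drivers and problem sizes

Model A and Model B use 1,000 individuals per sex per replicate (the
scale at which the design is usually illustrated) and default to 500
replicates per grid point, giving Monte-Carlo SEs near 0.002 on the
replicate-mean slope; grids are C ∈ {0.1, …, 0.9} (Model A) and
Ci ∈ {0, 0.1, …, 0.5}² (Model B, 36 cells). Replicates are vectorised
across the replicate axis, so a full grid runs in seconds. The analytic
oracles

    Model A: β_XY + β_EY·β_EX·2V_E(1−ρ) / (β_EX²·2V_E(1−ρ) + 2V_eX)
    Model B: β1 − β2·C1·C2/(1 − C1²)

were verified by brute-force simulation (3,000 replicates per probe
cell) before being frozen into tests; simulation grids agree with them
within 3 Monte-Carlo SEs at every cell. Model A's default calibration
(V_E = 1, β_EX = 0.5, V_eX = 0.75, β_XY = β_EY = 0.3, V_eY = 1) is
chosen so the confounded population slope is exactly 0.45 and the causal
effect 0.30, the two endpoints of the design's operating curve; Model
B's default β1 = β2 = 1 with unit variances makes the relative bias
C1·C2/(1−C1²), 13.33% at (0.5, 0.2).

The end-to-end shrinkage pipeline defaults to 4,000 spouse pairs, 2,000
sibling families, 20 variants and 100 random-pair replicates; tests run
a reduced 1,500/800/20-replicate version. Discovery weights are the
generator's true effects plus small N(0, 0.02²) noise, standing in for
an external discovery GWAS. The delta-method coverage check uses 2,000
replicates of a 5,000-pair, 20-variant harness with a known
multiplicative attenuation; the null-centering check uses 200 replicates
of the same harness at zero attenuation.

The negative control assorts on age only (weight 2 on standardised age),
gives the continuous outcome 0.8 units per year of age with outcome
noise SD 15, and thresholds a liability with a 0.5 standardised-age
weight at 10% prevalence. Spouse pairs show compressed age gaps relative
to random pairs, and — because age has no collider path to the outcomes
— spouse-pair and random-pair age-effect estimates agree. Random-pair
age-gap quartiles are pooled across replicates.

## What the synthetic cohorts do and do not emulate

The generator reproduces the statistical skeleton the analyses assume:
additive phenotypes, exact dosages, a single latent assortment channel,
two-way stratification, Mendelian siblings, a common-pair environment.
It does not emulate linkage disequilibrium, multi-generational
equilibrium assortment (which builds cross-chromosome genetic
correlations), correlated assortment factors, social homogamy as a
process distinct from score matching, measurement error, participation
bias, or real principal-component structure. Passing tests therefore
demonstrate the estimators' behaviour under the stated models — not that
real spousal data satisfy those models.

## Degenerate inputs and tie-breaking

Zero families or zero random replicates yield empty tables, not errors.
Ties in assortment scores break by stable input order. Zero shared-
environment SD is an exact identity. Validation errors name the
offending field. Constant design columns are pruned (logged); rank
deficiency beyond that is an error listing the collinear columns.
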