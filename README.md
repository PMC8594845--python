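# wsplab

Simulation and analysis toolkit for **within-spouse-pair (WSP) association
models under assortative mating**.

Comparing spouses — regressing the within-couple difference of an outcome
on the within-couple difference of an exposure or genotype — is an
attractive epidemiological design: any factor the partners share (the
household environment, local social context, ancestry) cancels from the
differences, so the design can remove confounding that plagues studies of
unrelated individuals. But spouses are not paired at random. People assort
on phenotypes, and conditioning on an assorted pairing is conditioning on
a collider: traits that jointly drive partner choice become negatively
correlated *within* couples even when they are independent in the
population. `wsplab` exists to quantify both faces of the design — how
much confounding spousal comparisons remove, and how much collider bias
they introduce — on fully synthetic cohorts where the truth is known.

## The models

**Within-pair difference model.** A phenotype is modelled additively,
`P = G + E + Age + Sex + ε`, where `G` is a sum of per-variant dosage
effects and `E` an unmeasured environmental confounder. For a male–female
pair *K* the model of analysis is

```
PhenotypeDif_K ~ GenotypeDif_K + AgeDif_K + Sex_K(index)
```

one observation per couple; shared-environment terms are identical within
a pair and drop out of every difference exactly. Binary outcomes are
handled by reorienting each pair so the outcome difference is 0 or 1 and
fitting unconditional logistic regression.

**Assortment.** Spouse pairs are formed by rank-matching males and
females on a latent compatibility score `A`: sort each sex descending on
`A` and match by rank. If a trait `V` has `Corr(V, A) = C`, matching
induces a within-couple correlation for `V` of about `C²`.

**Deconfounding (Model A).** `X → Y` confounded by `E`, with
`Corr(E, A) = C`. The expected WSP slope at induced spousal confounder
correlation ρ is

```
β_WSP(ρ) = β_XY + β_EY · β_EX · 2·Var(E)·(1−ρ) / (β_EX²·2·Var(E)·(1−ρ) + 2·Var(e_X))
```

moving from the confounded population slope (0.45 under the default
calibration) to the causal coefficient (0.30) as ρ → 1.

**Collider bias (Model B).** Two independent exposures `X1, X2` both
affect `Y` and both drive assortment (`Corr(Xi, A) = Ci`). Conditional on
the matched score, `Cov(X1, X2 | A) = −C1·C2`, so the WSP slope for `X1`
is

```
β_WSP = β1 − β2 · C1·C2 / (1 − C1²)
```

a downward bias of `C1·C2/(1−C1²)` relative to `β1` when all coefficients
are positive — about 13% at `(C1, C2) = (0.5, 0.2)`.

**IVW shrinkage.** Per-variant within-pair estimates `(β_j, SE_j)` are
combined against discovery-GWAS effect sizes `w_j`:

```
β_IVW = Σ w_j β_j / SE_j²  ÷  Σ w_j² / SE_j²        SE_IVW = (Σ w_j² / SE_j²)^(−1/2)
```

Shrinkage of a within-pair model against a random-pair reference is
`100·(1 − β_comparison / β_reference)` with a first-order delta-method SE
(zero covariance assumed), and heterogeneity between two shrinkage
estimates uses the normal difference-of-two-means test. The random-pair
null re-pairs the same individuals uniformly at random (100 replicates by
default) and summarises per-variant fits by medians.

## Worked example

```python
from wsplab import ModelBConfig, run_model_b

cfg = ModelBConfig(corr_X1_A=0.5, corr_X2_A=0.2, n_replicates=500, seed=1)
grid = run_model_b(cfg, grid=[(0.5, 0.2)])
print(grid.round(4).to_string(index=False))
```

```
 C1  C2  mean_estimate  mc_se  relative_bias_pct  analytic_slope  n_replicates
0.5 0.2         0.8711 0.0023            12.8921          0.8667           500
```

With equal unit effects of both exposures, the mean within-pair slope for
`X1` across 500 replicates of 1,000 couples is 0.871 instead of the true
1.0 — a 12.9% downward bias (Monte-Carlo SE 0.0023 on the slope), against
the closed-form large-n value 0.8667 (13.33%). Spousal correlations of
0.5 and 0.2 are about what is reported for educational attainment and
height, so an education effect estimated within couples would be
attenuated by roughly this much if height also influences the outcome.

The deconfounding side of the design:

```python
from wsplab import ModelAConfig, SimulationSeed, population_slope_model_a, run_model_a

slope = population_slope_model_a(ModelAConfig(), 100_000, SimulationSeed(1, "pop-slope"))
print(f"unadjusted population slope: {slope:.3f}")
print(run_model_a(ModelAConfig(seed=1, n_replicates=200), grid=[0.1, 0.5, 0.9])
      .round(4).to_string(index=False))
```

```
unadjusted population slope: 0.453
  C  mean_estimate  mc_se  relative_bias_pct  measured_rho_E  analytic_slope  n_replicates
0.1         0.4490 0.0024            49.6602          0.0120          0.4489           200
0.5         0.4178 0.0025            39.2735          0.2521          0.4200           200
0.9         0.3399 0.0024            13.2900          0.8091          0.3357           200
```

The population regression of outcome on exposure is confounded upward to
0.45 (truth 0.30). As assortment on the confounder strengthens, the WSP
estimate falls toward the causal value; at `C = 0.9` the induced spousal
confounder correlation is 0.81 (`≈ C²`) and the estimate is 0.34. The
`relative_bias_pct` column is the remaining bias as a percentage of the
causal coefficient.

A command-line workbench wraps the same machinery
(`wsplab simulate | pair | diff | fit | ivw | shrinkage | model-a |
model-b | negative-control | pipeline`); every run writes its outputs as
TSV/JSON plus a manifest recording the resolved configuration, seed and
input checksums.

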