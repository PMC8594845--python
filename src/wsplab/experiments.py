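"""Simulation studies of the within-spouse-pair (WSP) design.

Two generative models probe the design's two headline behaviours:

* **Model A (deconfounding).** An exposure X affects an outcome Y, both
  also driven by an unmeasured confounder E; spouses are rank-matched on
  an assortment score A with Corr(E, A) = C. As the induced spousal
  correlation for E grows, the WSP slope of the Y-difference on the
  X-difference moves from the confounded population slope toward the
  causal coefficient — matching on the confounder cancels it from the
  differences.

* **Model B (collider bias).** Two marginally independent exposures X1
  and X2 both affect Y and both drive assortment (Corr(Xi, A) = Ci).
  Conditioning on the assorted pairing makes the within-pair X1 and X2
  differences negatively correlated, so the WSP slope for X1 is biased
  away from beta1; with all coefficients positive the bias is downward
  attenuation.

Both drivers carry closed-form oracles for the large-n expected WSP
slope, derived from the conditional covariance structure given the
matched score, and report Monte-Carlo SEs alongside replicate means.

The module also provides an end-to-end shrinkage pipeline on a
stratified, assorted cohort (the genetic-association use of the design)
and a negative-control analysis of age effects.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import SimulationSeed
from .cohort import (
    PhenotypeModelParams,
    StratificationParams,
    add_binary_phenotype,
    simulate_individuals,
    simulate_sibling_cohort,
)
from .pair_models import (
    compute_pair_differences,
    estimates_to_frame,
    fit_pair_regression,
    orient_binary_pairs,
    summarize_random_pair_fits,
)
from .pairing import generate_random_pairs, rank_match_pairs
from .shrinkage import (
    IVWResult,
    ShrinkageResult,
    compute_shrinkage,
    difference_of_means_test,
    ivw_combine,
    join_weights,
)

__all__ = [
    "ModelAConfig",
    "ModelBConfig",
    "ShrinkagePipelineConfig",
    "NegativeControlConfig",
    "run_model_a",
    "run_model_b",
    "analytic_model_a_slope",
    "analytic_model_b_slope",
    "population_slope_model_a",
    "run_shrinkage_pipeline",
    "run_negative_control",
    "simulated_pipeline_shrinkage",
    "no_intercept_slope",
    "MODEL_A_GRID",
    "MODEL_B_GRID",
]

#: grid of Corr(E, A) values for the deconfounding study
MODEL_A_GRID = tuple(round(0.1 * k, 1) for k in range(1, 10))

#: grid of (Corr(X1,A), Corr(X2,A)) values for the collider study
MODEL_B_GRID = tuple(
    (round(0.1 * i, 1), round(0.1 * j, 1)) for i in range(6) for j in range(6)
)


@dataclass(frozen=True)
class ModelAConfig:
    """Confounded exposure-outcome model with assortment on the confounder.

    Default calibration: Var(X) = 1 with half its variance from E, causal
    effect 0.30 and confounder path 0.30, so the unadjusted population
    slope of Y on X is analytically 0.45 — the confounded and unbiased
    endpoints of the design's operating curve.
    """

    corr_E_A: float = 0.0
    beta_E_on_X: float = 0.5
    beta_E_on_Y: float = 0.3
    beta_X_on_Y: float = 0.3
    var_E: float = 1.0
    var_eX: float = 0.75
    var_eY: float = 1.0
    n_per_sex: int = 1000
    n_replicates: int = 500
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.corr_E_A < 1.0:
            raise ValueError(f"corr_E_A must be in [0, 1), got {self.corr_E_A}")
        for name in ("var_E", "var_eX", "var_eY"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_per_sex < 1 or self.n_replicates < 1:
            raise ValueError("n_per_sex and n_replicates must be >= 1")


@dataclass(frozen=True)
class ModelBConfig:
    """Two independent exposures driving both the outcome and assortment."""

    corr_X1_A: float = 0.5
    corr_X2_A: float = 0.2
    beta1: float = 1.0
    beta2: float = 1.0
    noise_sd: float = 1.0
    n_per_sex: int = 1000
    n_replicates: int = 500
    seed: int = 0

    def validate(self) -> None:
        for name in ("corr_X1_A", "corr_X2_A"):
            value = getattr(self, name)
            if not 0.0 <= value < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {value}")
        if self.corr_X1_A**2 + self.corr_X2_A**2 >= 1.0:
            raise ValueError(
                "infeasible correlation structure: need C1^2 + C2^2 < 1, got "
                f"C1={self.corr_X1_A}, C2={self.corr_X2_A}"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_per_sex < 1 or self.n_replicates < 1:
            raise ValueError("n_per_sex and n_replicates must be >= 1")


def no_intercept_slope(x: np.ndarray, y: np.ndarray) -> float:
    """OLS slope of y on x through the origin: sum(xy) / sum(x^2).

    The pure-difference WSP regression has no intercept (all regressors
    antisymmetric), so this closed form equals ``fit_pair_regression``
    with no covariates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.sum(x * y) / np.sum(x * x))


def _batch_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise no-intercept slopes for (replicates, n) arrays."""
    return np.sum(x * y, axis=1) / np.sum(x * x, axis=1)


def _sort_rows_desc(key: np.ndarray, *arrays: np.ndarray) -> tuple:
    order = np.argsort(-key, axis=1, kind="stable")
    return tuple(np.take_along_axis(a, order, axis=1) for a in arrays)


def analytic_model_a_slope(config: ModelAConfig, rho_E: float) -> float:
    """Expected WSP slope of Y-diff on X-diff at spousal confounder
    correlation ``rho_E``.

    The difference variables satisfy X* = bEX E* + eX*, Y* = bXY X* +
    bEY E* + eY* with Var(E*) = 2 var_E (1 - rho); the slope is the causal
    coefficient plus the confounding term scaled by the remaining share of
    E* variance in X*. At rho = 1 the confounder cancels exactly and the
    causal coefficient is returned.
    """
    if not 0.0 <= rho_E <= 1.0:
        raise ValueError(f"rho_E must be in [0, 1], got {rho_E}")
    bEX, bEY = config.beta_E_on_X, config.beta_E_on_Y
    vE_star = 2.0 * config.var_E * (1.0 - rho_E)
    numerator = bEY * bEX * vE_star
    denominator = bEX**2 * vE_star + 2.0 * config.var_eX
    return float(config.beta_X_on_Y + numerator / denominator)


def analytic_model_b_slope(C1: float, C2: float, beta1: float, beta2: float) -> float:
    """Large-n expected WSP slope for exposure 1 under exact matching on A.

    Conditional on the matched score, Cov(X1, X2 | A) = -C1 C2 and
    Var(X1 | A) = 1 - C1^2, giving slope = beta1 - beta2 C1 C2 / (1 - C1^2).
    With C2 = 0 there is no collider path and the slope is beta1 exactly.
    """
    if C1**2 >= 1.0:
        raise ValueError("C1^2 must be < 1")
    if C1**2 + C2**2 >= 1.0:
        raise ValueError("infeasible correlation structure: need C1^2 + C2^2 < 1")
    return float(beta1 - beta2 * C1 * C2 / (1.0 - C1**2))


def _simulate_model_a_point(
    config: ModelAConfig, C: float, rng: np.random.Generator
) -> tuple:
    """Replicate-wise WSP slopes and measured spousal E correlations at one C."""
    R, n = config.n_replicates, config.n_per_sex
    out_slopes = np.empty(R)
    out_rho = np.empty(R)

    def _draw_sex():
        e0 = rng.standard_normal((R, n))
        z = rng.standard_normal((R, n))
        A = C * e0 + np.sqrt(1.0 - C**2) * z
        E = np.sqrt(config.var_E) * e0
        X = config.beta_E_on_X * E + np.sqrt(config.var_eX) * rng.standard_normal((R, n))
        Y = (
            config.beta_X_on_Y * X
            + config.beta_E_on_Y * E
            + np.sqrt(config.var_eY) * rng.standard_normal((R, n))
        )
        return _sort_rows_desc(A, E, X, Y)

    Em, Xm, Ym = _draw_sex()
    Ef, Xf, Yf = _draw_sex()
    out_slopes = _batch_slopes(Xm - Xf, Ym - Yf)
    for r in range(R):
        out_rho[r] = np.corrcoef(Em[r], Ef[r])[0, 1]
    return out_slopes, out_rho


def run_model_a(
    config: ModelAConfig, grid: Optional[Sequence[float]] = None
) -> pd.DataFrame:
    """Deconfounding study: WSP slope across a grid of Corr(E, A) values.

    Per grid point and replicate, 1,000 individuals per sex are drawn,
    rank-matched on A, and the Y-difference is regressed on the
    X-difference with no adjustment for E. The induced (measured) spousal
    correlation for E is reported alongside the assortment parameter C,
    since the two scales differ (quantile matching induces roughly C^2).
    """
    config.validate()
    grid = MODEL_A_GRID if grid is None else tuple(grid)
    for C in grid:
        if not 0.0 <= C < 1.0:
            raise ValueError(f"grid value {C} outside [0, 1)")
    root = SimulationSeed(config.seed, "model-a")
    rows = []
    for C in grid:
        rng = root.child(f"C={C}").rng()
        slopes, rho = _simulate_model_a_point(config, C, rng)
        mean_est = float(np.mean(slopes))
        mc_se = float(np.std(slopes, ddof=1) / np.sqrt(len(slopes)))
        rho_mean = float(np.mean(rho))
        rows.append(
            {
                "C": C,
                "mean_estimate": mean_est,
                "mc_se": mc_se,
                "relative_bias_pct": 100.0
                * (mean_est - config.beta_X_on_Y)
                / config.beta_X_on_Y,
                "measured_rho_E": rho_mean,
                "analytic_slope": analytic_model_a_slope(config, C**2),
                "n_replicates": config.n_replicates,
            }
        )
    return pd.DataFrame(rows)


def _simulate_model_b_point(
    config: ModelBConfig, C1: float, C2: float, rng: np.random.Generator
) -> np.ndarray:
    R, n = config.n_replicates, config.n_per_sex
    resid = np.sqrt(1.0 - C1**2 - C2**2)

    def _draw_sex():
        X1 = rng.standard_normal((R, n))
        X2 = rng.standard_normal((R, n))
        A = C1 * X1 + C2 * X2 + resid * rng.standard_normal((R, n))
        Y = (
            config.beta1 * X1
            + config.beta2 * X2
            + config.noise_sd * rng.standard_normal((R, n))
        )
        return _sort_rows_desc(A, X1, Y)

    X1m, Ym = _draw_sex()
    X1f, Yf = _draw_sex()
    return _batch_slopes(X1m - X1f, Ym - Yf)


def run_model_b(
    config: ModelBConfig, grid: Optional[Sequence[tuple]] = None
) -> pd.DataFrame:
    """Collider study: WSP slope for X1 across a grid of (C1, C2) values.

    (X1, X2, A) are jointly normal with Corr(X1, X2) = 0 and
    Corr(Xi, A) = Ci; pairs are rank-matched on A and the Y-difference is
    regressed on the X1-difference. Relative bias is reported as a
    percentage of the true coefficient beta1.
    """
    config.validate()
    if grid is None:
        grid = MODEL_B_GRID
    for C1, C2 in grid:
        if C1**2 + C2**2 >= 1.0:
            raise ValueError(
                f"infeasible grid point ({C1}, {C2}): need C1^2 + C2^2 < 1"
            )
    root = SimulationSeed(config.seed, "model-b")
    rows = []
    for C1, C2 in grid:
        rng = root.child(f"C1={C1}/C2={C2}").rng()
        slopes = _simulate_model_b_point(config, C1, C2, rng)
        mean_est = float(np.mean(slopes))
        mc_se = float(np.std(slopes, ddof=1) / np.sqrt(len(slopes)))
        rows.append(
            {
                "C1": C1,
                "C2": C2,
                "mean_estimate": mean_est,
                "mc_se": mc_se,
                "relative_bias_pct": 100.0 * (1.0 - mean_est / config.beta1),
                "analytic_slope": analytic_model_b_slope(
                    C1, C2, config.beta1, config.beta2
                ),
                "n_replicates": config.n_replicates,
            }
        )
    return pd.DataFrame(rows)


def population_slope_model_a(
    config: ModelAConfig, n_individuals: int, seed: SimulationSeed
) -> float:
    """Unadjusted population OLS slope of Y on X in the Model A generator.

    Under the default calibration the analytic value is
    beta_X_on_Y + beta_E_on_Y * beta_E_on_X * var_E / Var(X) = 0.45.
    """
    config.validate()
    if n_individuals < 3:
        raise ValueError("need at least 3 individuals")
    rng = seed.rng()
    E = np.sqrt(config.var_E) * rng.standard_normal(n_individuals)
    X = config.beta_E_on_X * E + np.sqrt(config.var_eX) * rng.standard_normal(
        n_individuals
    )
    Y = (
        config.beta_X_on_Y * X
        + config.beta_E_on_Y * E
        + np.sqrt(config.var_eY) * rng.standard_normal(n_individuals)
    )
    return float(stats.linregress(X, Y).slope)


# ---------------------------------------------------------------------------
# Table-1-style shrinkage pipeline on a stratified, assorted cohort
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ShrinkagePipelineConfig:
    """End-to-end genetic-association shrinkage study.

    A two-subpopulation cohort with a phenotype offset makes ancestry a
    confounder of every frequency-divergent variant; spouses assort on
    ancestry (via pc1), so within-spouse and within-sibling differences
    are largely free of the stratification signal while random pairs
    retain it. Per-variant difference regressions feed IVW combination
    and shrinkage of the within-pair models against the random-pair
    median reference, with and without ancestry-difference adjustment of
    the reference.
    """

    n_pairs: int = 4000
    n_sibling_families: int = 2000
    variant_count: int = 20
    allele_freq_range: tuple = (0.2, 0.8)
    effect_range: tuple = (0.05, 0.15)
    weight_noise_sd: float = 0.02
    noise_sd: float = 1.0
    age_effect: float = 0.02
    sex_effect: float = 0.2
    subpop_phenotype_offset: float = 0.5
    freq_divergence: float = 0.5
    ancestry_noise_sd: float = 0.1
    assortment_ancestry_weight: float = 3.0
    assortment_noise_sd: float = 1.0
    n_random_replicates: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.variant_count < 1:
            raise ValueError("variant_count must be >= 1")
        if self.n_pairs < 10 or self.n_sibling_families < 10:
            raise ValueError("n_pairs and n_sibling_families must be >= 10")
        if self.n_random_replicates < 1:
            raise ValueError("n_random_replicates must be >= 1")


def _pc_diff_columns() -> list:
    return [f"pc{i}_diff" for i in range(1, 11)]


def run_shrinkage_pipeline(config: ShrinkagePipelineConfig) -> tuple:
    """Run the full shrinkage study; returns ``(table, details)``.

    ``table`` has one row per reference covariate set (``no_pc``,
    ``pc1-10``) with WSP and within-sibship shrinkage (percent, 95% CI)
    against the random-pair median reference and the heterogeneity P for
    the two shrinkage estimates. ``details`` carries the per-variant
    estimate frames and IVW results.
    """
    config.validate()
    root = SimulationSeed(config.seed, "pipeline")

    rng_v = root.child("variants").rng()
    freqs = rng_v.uniform(*config.allele_freq_range, config.variant_count)
    effects = rng_v.uniform(*config.effect_range, config.variant_count)
    weights = effects + rng_v.normal(0.0, config.weight_noise_sd, config.variant_count)
    variants = [f"g_{j + 1}" for j in range(config.variant_count)]
    weights_frame = pd.DataFrame({"variant": variants, "weight": weights})

    params = PhenotypeModelParams(
        variant_count=config.variant_count,
        allele_freqs=tuple(freqs),
        variant_effects=tuple(effects),
        age_effect=config.age_effect,
        sex_effect=config.sex_effect,
        noise_sd=config.noise_sd,
        stratification=StratificationParams(
            freq_divergence=config.freq_divergence,
            subpop_phenotype_offset=config.subpop_phenotype_offset,
            ancestry_noise_sd=config.ancestry_noise_sd,
        ),
        assortment_weights={"pc1": config.assortment_ancestry_weight},
        assortment_noise_sd=config.assortment_noise_sd,
    )

    cohort = simulate_individuals(params, config.n_pairs, root.child("cohort"))
    spouse_pairs = rank_match_pairs(cohort, "A")
    random_pairs = generate_random_pairs(
        spouse_pairs, cohort, config.n_random_replicates, root.child("random-pairs")
    )
    sib_cohort, sib_pairs = simulate_sibling_cohort(
        params, config.n_sibling_families, root.child("siblings")
    )

    pcs = [f"pc{i}" for i in range(1, 11)]
    outcome = params.phenotype_column

    wsp_diffs = compute_pair_differences(
        cohort, spouse_pairs, outcome, variants, covariates=["age"]
    )
    wsp_estimates = fit_pair_regression(
        wsp_diffs, variants, covariates=["age_diff", "index_sex"], model_label="wsp"
    )

    sib_diffs = compute_pair_differences(
        sib_cohort, sib_pairs, outcome, variants, covariates=["age", "sex"]
    )
    sib_estimates = fit_pair_regression(
        sib_diffs, variants, covariates=["age_diff", "sex_diff"], model_label="sibling"
    )

    base_cov = ["age_diff", "index_sex"]
    adj_cov = base_cov + _pc_diff_columns()
    random_reps = {"no_pc": [], "pc1-10": []}
    for r in range(config.n_random_replicates):
        rep_pairs = random_pairs[random_pairs["replicate"] == r]
        rep_diffs = compute_pair_differences(
            cohort, rep_pairs, outcome, variants, covariates=["age"] + pcs
        )
        random_reps["no_pc"].append(
            fit_pair_regression(
                rep_diffs, variants, covariates=base_cov, model_label="random_pair"
            )
        )
        random_reps["pc1-10"].append(
            fit_pair_regression(
                rep_diffs, variants, covariates=adj_cov, model_label="random_pair"
            )
        )

    wsp_frame = join_weights(estimates_to_frame(wsp_estimates), weights_frame)
    sib_frame = join_weights(estimates_to_frame(sib_estimates), weights_frame)
    ivw_wsp = ivw_combine(wsp_frame)
    ivw_sib = ivw_combine(sib_frame)

    rows = []
    details = {
        "weights": weights_frame,
        "wsp_estimates": wsp_frame,
        "sibling_estimates": sib_frame,
        "ivw": {"wsp": ivw_wsp, "sibling": ivw_sib},
        "true_effects": pd.DataFrame({"variant": variants, "effect": effects}),
    }
    for cov_set, reps in random_reps.items():
        median_estimates = summarize_random_pair_fits(reps)
        ref_frame = join_weights(estimates_to_frame(median_estimates), weights_frame)
        ivw_ref = ivw_combine(ref_frame)
        shrink_wsp = compute_shrinkage(
            ivw_ref, ivw_wsp, reference_label=f"random_pair[{cov_set}]",
            comparison_label="wsp",
        )
        shrink_sib = compute_shrinkage(
            ivw_ref, ivw_sib, reference_label=f"random_pair[{cov_set}]",
            comparison_label="sibling",
        )
        het_z, het_p = difference_of_means_test(
            (shrink_wsp.shrinkage_pct, shrink_wsp.se_pct),
            (shrink_sib.shrinkage_pct, shrink_sib.se_pct),
        )
        details[f"ivw_random[{cov_set}]"] = ivw_ref
        details[f"random_median[{cov_set}]"] = ref_frame
        details[f"shrinkage_wsp[{cov_set}]"] = shrink_wsp
        details[f"shrinkage_sibling[{cov_set}]"] = shrink_sib
        rows.append(
            {
                "phenotype": params.phenotype_name,
                "n_snps": config.variant_count,
                "covariates": cov_set,
                "wsp_shrinkage_pct": shrink_wsp.shrinkage_pct,
                "wsp_ci_low": shrink_wsp.ci_low_pct,
                "wsp_ci_high": shrink_wsp.ci_high_pct,
                "sibling_shrinkage_pct": shrink_sib.shrinkage_pct,
                "sibling_ci_low": shrink_sib.ci_low_pct,
                "sibling_ci_high": shrink_sib.ci_high_pct,
                "het_z": het_z,
                "het_p": het_p,
            }
        )
    return pd.DataFrame(rows), details


# ---------------------------------------------------------------------------
# Negative control: age effects on a continuous and a binary outcome
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NegativeControlConfig:
    """Age as the exposure, with assortment on age only.

    Age cannot be caused by anything downstream, so spouse-pair and
    random-pair estimates of the age effect should agree unless collider
    bias from age assortment distorts the spouse model. The continuous
    outcome receives ``age_effect`` units per year; the binary outcome is
    a liability threshold (default 10% prevalence) on a liability with an
    age component.
    """

    n_pairs: int = 4000
    age_effect: float = 0.8
    outcome_noise_sd: float = 15.0
    binary_age_weight: float = 0.5
    binary_prevalence: float = 0.10
    assortment_age_weight: float = 2.0
    assortment_noise_sd: float = 1.0
    n_random_replicates: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.n_pairs < 10:
            raise ValueError("n_pairs must be >= 10")
        if not 0 < self.binary_prevalence < 1:
            raise ValueError("binary_prevalence must be in (0, 1)")
        if self.n_random_replicates < 1:
            raise ValueError("n_random_replicates must be >= 1")


def _age_gap_summary(cohort: pd.DataFrame, pairs: pd.DataFrame) -> dict:
    ages = cohort.set_index("id")["age"]
    gap = np.abs(
        ages.loc[pairs["index_id"]].to_numpy() - ages.loc[pairs["partner_id"]].to_numpy()
    )
    q1, med, q3 = np.percentile(gap, [25, 50, 75])
    return {"median": float(med), "q1": float(q1), "q3": float(q3)}


def run_negative_control(config: NegativeControlConfig) -> dict:
    """Estimate age effects within spouse pairs and random pairs.

    Returns per-sample age-gap summaries (median, Q1, Q3 of the absolute
    within-pair age difference; random-pair gaps are pooled across
    replicates) and the within-pair age-effect estimates: a linear slope
    for the continuous outcome and an odds ratio for the binary outcome,
    random-pair values summarised by the across-replicate median.
    """
    config.validate()
    root = SimulationSeed(config.seed, "negative-control")

    params = PhenotypeModelParams(
        variant_count=0,
        age_effect=config.age_effect,
        noise_sd=config.outcome_noise_sd,
        phenotype_name="cont",
        assortment_weights={"age": config.assortment_age_weight},
        assortment_noise_sd=config.assortment_noise_sd,
    )
    cohort = simulate_individuals(params, config.n_pairs, root.child("cohort"))

    # binary outcome: liability with an age component, thresholded
    rng = root.child("binary").rng()
    age = cohort["age"].to_numpy()
    z_age = (age - age.mean()) / age.std()
    cohort = cohort.assign(
        pheno_liability=config.binary_age_weight * z_age + rng.standard_normal(len(cohort))
    )
    cohort = add_binary_phenotype(cohort, "liability", "bin", config.binary_prevalence)

    spouse_pairs = rank_match_pairs(cohort, "A")
    random_pairs = generate_random_pairs(
        spouse_pairs, cohort, config.n_random_replicates, root.child("random-pairs")
    )

    def _linear(pairs, label):
        diffs = compute_pair_differences(cohort, pairs, "pheno_cont", ["age"])
        return fit_pair_regression(diffs, ["age"], model_label=label)[0]

    def _logistic(pairs, label):
        diffs = compute_pair_differences(cohort, pairs, "pheno_bin", ["age"])
        oriented = orient_binary_pairs(diffs)
        return fit_pair_regression(
            oriented, ["age"], family="logistic", model_label=label
        )[0]

    wsp_lin = _linear(spouse_pairs, "wsp")
    wsp_log = _logistic(spouse_pairs, "wsp")

    lin_reps, log_reps = [], []
    for r in range(config.n_random_replicates):
        rep = random_pairs[random_pairs["replicate"] == r]
        lin_reps.append([_linear(rep, "random_pair")])
        log_reps.append([_logistic(rep, "random_pair")])
    rand_lin = summarize_random_pair_fits(lin_reps)[0]
    rand_log = summarize_random_pair_fits(log_reps)[0]

    def _summary(lin, log):
        return {
            "linear_beta": lin.beta,
            "linear_se": lin.se,
            "linear_ci": (lin.beta - 1.96 * lin.se, lin.beta + 1.96 * lin.se),
            "odds_ratio": float(np.exp(log.beta)),
            "or_ci": (
                float(np.exp(log.beta - 1.96 * log.se)),
                float(np.exp(log.beta + 1.96 * log.se)),
            ),
            "logistic_beta": log.beta,
            "logistic_se": log.se,
        }

    return {
        "spouse": {
            "age_gap": _age_gap_summary(cohort, spouse_pairs),
            **_summary(wsp_lin, wsp_log),
        },
        "random": {
            "age_gap": _age_gap_summary(cohort, random_pairs),
            **_summary(rand_lin, rand_log),
        },
        "n_pairs": config.n_pairs,
        "n_random_replicates": config.n_random_replicates,
    }


# ---------------------------------------------------------------------------
# Scaled-down synthetic pipeline with known true shrinkage (calibration aid)
# ---------------------------------------------------------------------------


def simulated_pipeline_shrinkage(
    n_pairs: int,
    n_variants: int,
    true_shrinkage_pct: float,
    seed: SimulationSeed,
    noise_sd: float = 1.0,
) -> ShrinkageResult:
    """One replicate of a pipeline whose true shrinkage is known exactly.

    Two samples share variant effects; in the comparison sample every
    effect is attenuated by the known factor. Each variant's effect is
    estimated by a no-intercept OLS difference regression (closed form,
    classical SE) on its own independent sample of pair differences, so
    the per-variant estimates are independent — the sampling model the
    IVW formulas assume. The estimates feed IVW combination and the
    delta-method shrinkage; used to check SE calibration and CI coverage
    of the shrinkage machinery against a ground truth the full generative
    pipeline cannot pin down analytically.
    """
    rng = seed.rng()
    freqs = rng.uniform(0.2, 0.8, n_variants)
    effects = rng.uniform(0.1, 0.3, n_variants)
    factor = 1.0 - true_shrinkage_pct / 100.0

    def _sample(beta_vec: np.ndarray) -> pd.DataFrame:
        g1 = rng.binomial(2, np.broadcast_to(freqs, (n_pairs, n_variants)))
        g2 = rng.binomial(2, np.broadcast_to(freqs, (n_pairs, n_variants)))
        x = (g1 - g2).astype(float)
        # one independent outcome vector per variant
        y = x * beta_vec + np.sqrt(2.0) * noise_sd * rng.standard_normal(
            (n_pairs, n_variants)
        )
        sxx = np.sum(x * x, axis=0)
        slopes = np.sum(x * y, axis=0) / sxx
        rss = np.sum(y**2, axis=0) - slopes**2 * sxx
        ses = np.sqrt(rss / (n_pairs - 1) / sxx)
        return pd.DataFrame(
            {
                "variant": [f"g_{j + 1}" for j in range(n_variants)],
                "weight": effects,
                "beta": slopes,
                "se": ses,
            }
        )

    reference = ivw_combine(_sample(effects))
    comparison = ivw_combine(_sample(effects * factor))
    return compute_shrinkage(
        reference, comparison, reference_label="reference", comparison_label="attenuated"
    )
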