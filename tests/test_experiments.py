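"""Simulation-study drivers against their closed-form oracles."""
import numpy as np
import pandas as pd
import pytest

from wsplab import (
    ModelAConfig,
    ModelBConfig,
    NegativeControlConfig,
    ShrinkagePipelineConfig,
    SimulationSeed,
    analytic_model_a_slope,
    analytic_model_b_slope,
    population_slope_model_a,
    run_model_a,
    run_model_b,
    run_negative_control,
    run_shrinkage_pipeline,
    simulated_pipeline_shrinkage,
)
from wsplab.experiments import no_intercept_slope


class TestModelAOracle:
    def test_full_confounder_matching_returns_causal_effect(self):
        cfg = ModelAConfig()
        assert analytic_model_a_slope(cfg, 1.0) == pytest.approx(cfg.beta_X_on_Y)

    def test_no_matching_returns_confounded_population_slope(self):
        # default calibration: 0.30 causal + 0.15 confounding = 0.45
        assert analytic_model_a_slope(ModelAConfig(), 0.0) == pytest.approx(0.45)

    def test_intermediate_value(self):
        assert analytic_model_a_slope(ModelAConfig(), 0.5) == pytest.approx(
            0.3857, abs=1e-4
        )

    def test_monotone_decreasing_in_correlation(self):
        cfg = ModelAConfig()
        values = [analytic_model_a_slope(cfg, r) for r in np.linspace(0, 1, 11)]
        assert all(a > b for a, b in zip(values, values[1:]))


class TestModelBOracle:
    def test_no_collider_path_when_either_correlation_zero(self):
        assert analytic_model_b_slope(0.0, 0.4, 1.0, 1.0) == pytest.approx(1.0)
        assert analytic_model_b_slope(0.4, 0.0, 1.0, 1.0) == pytest.approx(1.0)

    def test_education_height_calibration(self):
        # C1 = 0.5, C2 = 0.2: slope 0.8667, i.e. 13.33% downward bias
        slope = analytic_model_b_slope(0.5, 0.2, 1.0, 1.0)
        assert slope == pytest.approx(0.86667, abs=1e-4)
        assert 100 * (1 - slope) == pytest.approx(13.33, abs=0.01)

    def test_symmetric_strong_assortment(self):
        assert analytic_model_b_slope(0.5, 0.5, 1.0, 1.0) == pytest.approx(
            2.0 / 3.0, abs=1e-9
        )

    def test_infeasible_structure_rejected(self):
        with pytest.raises(ValueError):
            analytic_model_b_slope(0.8, 0.7, 1.0, 1.0)


def test_model_a_grid_matches_oracle():
    cfg = ModelAConfig(seed=101, n_replicates=150)
    grid = run_model_a(cfg, grid=[0.0, 0.5, 0.9])
    for _, row in grid.iterrows():
        assert row["mean_estimate"] == pytest.approx(
            row["analytic_slope"], abs=3 * row["mc_se"]
        )
    # estimate decreases as assortment on the confounder strengthens
    assert grid["mean_estimate"].is_monotonic_decreasing
    # measured spousal confounder correlation tracks C^2, not C
    assert grid.loc[2, "measured_rho_E"] == pytest.approx(0.81, abs=0.02)


def test_model_a_no_assortment_keeps_confounded_slope():
    cfg = ModelAConfig(seed=7, n_replicates=200)
    grid = run_model_a(cfg, grid=[0.0])
    assert grid.loc[0, "mean_estimate"] == pytest.approx(
        0.45, abs=max(0.01, 3 * grid.loc[0, "mc_se"])
    )


def test_model_b_collider_bias_down_13_percent():
    cfg = ModelBConfig(seed=5, n_replicates=200)
    grid = run_model_b(cfg, grid=[(0.5, 0.2)])
    assert grid.loc[0, "relative_bias_pct"] == pytest.approx(13.33, abs=1.5)


def test_model_b_no_bias_without_second_exposure_assortment():
    cfg = ModelBConfig(seed=5, n_replicates=100)
    grid = run_model_b(cfg, grid=[(0.5, 0.0), (0.3, 0.0)])
    for _, row in grid.iterrows():
        assert row["relative_bias_pct"] == pytest.approx(0.0, abs=3 * 100 * row["mc_se"])


def test_model_b_bias_monotone_in_assortment():
    cfg = ModelBConfig(seed=9, n_replicates=150)
    grid = run_model_b(cfg, grid=[(0.2, 0.2), (0.4, 0.2), (0.4, 0.4)])
    bias = grid["relative_bias_pct"].to_numpy()
    assert bias[0] < bias[1] < bias[2]
    assert (bias > 0).all()  # attenuation when all coefficients positive


def test_model_b_infeasible_grid_point_rejected_before_simulation():
    with pytest.raises(ValueError, match="infeasible"):
        run_model_b(ModelBConfig(seed=1, n_replicates=10), grid=[(0.9, 0.9)])


def test_population_slope_default_calibration():
    slope = population_slope_model_a(ModelAConfig(), 100_000, SimulationSeed(3, "pop"))
    assert slope == pytest.approx(0.45, abs=0.01)


def test_no_intercept_slope_matches_pair_regression():
    from wsplab import fit_pair_regression

    rng = np.random.default_rng(13)
    x = rng.standard_normal(50)
    y = 0.4 * x + rng.standard_normal(50)
    diffs = pd.DataFrame(
        {"pair_id": [f"p{i}" for i in range(50)], "outcome_diff": y, "x_diff": x,
         "index_sex": 1.0, "partner_sex": 0.0}
    )
    est = fit_pair_regression(diffs, ["x"], covariates=[])[0]
    assert no_intercept_slope(x, y) == pytest.approx(est.beta, abs=1e-12)


def test_determinism_of_drivers():
    cfg = ModelBConfig(seed=77, n_replicates=20)
    a = run_model_b(cfg, grid=[(0.3, 0.3)])
    b = run_model_b(cfg, grid=[(0.3, 0.3)])
    pd.testing.assert_frame_equal(a, b)


@pytest.fixture(scope="module")
def stratified_run():
    cfg = ShrinkagePipelineConfig(
        n_pairs=1500, n_sibling_families=800, n_random_replicates=20, seed=42
    )
    return run_shrinkage_pipeline(cfg)


class TestShrinkagePipeline:
    def test_stratification_produces_positive_wsp_shrinkage(self, stratified_run):
        table, _ = stratified_run
        row = table[table["covariates"] == "no_pc"].iloc[0]
        # ancestry-matched spouses difference away the stratification signal
        assert row["wsp_ci_low"] > 0
        assert row["sibling_ci_low"] > 0

    def test_ancestry_adjustment_attenuates_shrinkage(self, stratified_run):
        table, _ = stratified_run
        unadj = table[table["covariates"] == "no_pc"].iloc[0]
        adj = table[table["covariates"] == "pc1-10"].iloc[0]
        assert adj["wsp_shrinkage_pct"] < 0.5 * unadj["wsp_shrinkage_pct"]

    def test_wsp_ivw_near_truth(self, stratified_run):
        # with weights ~ true effects, the deconfounded IVW slope of beta
        # on weight is near 1
        _, details = stratified_run
        assert details["ivw"]["wsp"].beta_ivw == pytest.approx(1.0, abs=0.35)
        assert details["ivw_random[no_pc]"].beta_ivw > 1.5  # confounded

    def test_table_shape(self, stratified_run):
        table, _ = stratified_run
        assert set(table["covariates"]) == {"no_pc", "pc1-10"}
        assert (table["n_snps"] == 20).all()
        assert table["het_p"].between(0, 1).all()


def test_null_pipeline_shrinkage_centered_at_zero():
    # no attenuation: shrinkage estimates scatter around 0 across seeds
    values = [
        simulated_pipeline_shrinkage(
            2_000, 10, 0.0, SimulationSeed(s, "null-pipe")
        ).shrinkage_pct
        for s in range(30)
    ]
    t = np.mean(values) / (np.std(values, ddof=1) / np.sqrt(len(values)))
    assert abs(t) < 3.5


def test_synthetic_pipeline_recovers_known_shrinkage():
    res = simulated_pipeline_shrinkage(5_000, 20, 30.0, SimulationSeed(8, "known"))
    assert res.shrinkage_pct == pytest.approx(30.0, abs=3 * res.se_pct)


@pytest.fixture(scope="module")
def report():
    cfg = NegativeControlConfig(n_pairs=1500, n_random_replicates=10, seed=99)
    return run_negative_control(cfg)


class TestNegativeControl:
    def test_spouse_age_gaps_compressed_by_assortment(self, report):
        assert report["spouse"]["age_gap"]["median"] < report["random"]["age_gap"]["median"]

    def test_age_effect_agrees_between_samples(self, report):
        # no collider path to the outcome: both estimates near the true 0.8
        se = np.hypot(report["spouse"]["linear_se"], report["random"]["linear_se"])
        assert report["spouse"]["linear_beta"] == pytest.approx(
            report["random"]["linear_beta"], abs=3 * se
        )
        assert report["spouse"]["linear_beta"] == pytest.approx(0.8, abs=0.3)

    def test_binary_outcome_odds_ratio_above_one(self, report):
        assert report["spouse"]["odds_ratio"] > 1.0
        assert report["random"]["odds_ratio"] > 1.0
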