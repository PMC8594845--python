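"""Difference tables, binary orientation, and within-pair regression fits."""
import numpy as np
import pandas as pd
import pytest

from wsplab import (
    AssociationEstimate,
    PhenotypeModelParams,
    SimulationSeed,
    apply_shared_environment,
    compute_pair_differences,
    fit_pair_regression,
    orient_binary_pairs,
    rank_match_pairs,
    read_estimates,
    simulate_individuals,
    summarize_random_pair_fits,
    write_estimates,
)


def _toy_cohort():
    return pd.DataFrame(
        {
            "id": ["m1", "m2", "f1", "f2"],
            "sex": [1, 1, 0, 0],
            "age": [50.0, 60.0, 45.0, 62.0],
            "g_1": [2, 1, 0, 1],
            "pheno_y": [3.0, 1.0, 1.0, 2.0],
            "pheno_case": [1, 0, 0, 1],
        }
    )


def _toy_pairs():
    return pd.DataFrame(
        {
            "index_id": ["m1", "m2"],
            "partner_id": ["f1", "f2"],
            "pair_type": "spouse",
            "replicate": pd.array([pd.NA, pd.NA], dtype="Int64"),
        }
    )


def test_differences_are_index_minus_partner():
    diffs = compute_pair_differences(
        _toy_cohort(), _toy_pairs(), "pheno_y", ["g_1"], ["age"]
    )
    assert diffs["g_1_diff"].tolist() == [2.0, 0.0]
    assert diffs["outcome_diff"].tolist() == [2.0, -1.0]
    assert diffs["age_diff"].tolist() == [5.0, -2.0]
    assert diffs["index_sex"].tolist() == [1.0, 1.0]


def test_reversing_pair_order_negates_every_difference():
    pairs = _toy_pairs()
    flipped = pairs.rename(
        columns={"index_id": "partner_id", "partner_id": "index_id"}
    )
    a = compute_pair_differences(_toy_cohort(), pairs, "pheno_y", ["g_1"], ["age"])
    b = compute_pair_differences(_toy_cohort(), flipped, "pheno_y", ["g_1"], ["age"])
    for col in ("outcome_diff", "g_1_diff", "age_diff"):
        np.testing.assert_array_equal(a[col].to_numpy(), -b[col].to_numpy())
    np.testing.assert_array_equal(
        a["index_sex"].to_numpy(), 1 - b["index_sex"].to_numpy()
    )


def test_unknown_outcome_raises():
    with pytest.raises(ValueError, match="nonexistent"):
        compute_pair_differences(_toy_cohort(), _toy_pairs(), "nonexistent", ["g_1"])


def test_outcome_differences_invariant_to_shared_environment():
    params = PhenotypeModelParams(
        variant_count=1, allele_freqs=(0.5,), variant_effects=(0.3,)
    )
    seed = SimulationSeed(21, "se")
    cohort = simulate_individuals(params, 200, seed.child("cohort"))
    pairs = rank_match_pairs(cohort, "A")
    shifted = apply_shared_environment(cohort, pairs, 3.0, "y", seed.child("draw"))
    a = compute_pair_differences(cohort, pairs, "pheno_y", ["g_1"])
    b = compute_pair_differences(shifted, pairs, "pheno_y", ["g_1"])
    np.testing.assert_allclose(
        a["outcome_diff"], b["outcome_diff"], rtol=0, atol=1e-12
    )


class TestOrientBinaryPairs:
    def _diffs(self):
        cohort = _toy_cohort()
        pairs = _toy_pairs()
        return compute_pair_differences(cohort, pairs, "pheno_case", ["g_1"], ["age"])

    def test_partner_case_pairs_are_flipped(self):
        diffs = self._diffs()
        oriented = orient_binary_pairs(diffs)
        # pair (m2, f2): m2 control, f2 case -> flipped
        row = oriented[oriented["pair_id"] == "m2|f2"].iloc[0]
        assert row["outcome_diff"] == 1.0
        assert row["g_1_diff"] == 0.0  # was 0, negation preserves it
        assert row["age_diff"] == 2.0  # was -2, negated
        assert row["index_sex"] == 0.0  # the female case is now the index
        assert set(oriented["outcome_diff"]) <= {0.0, 1.0}

    def test_discordant_index_case_untouched(self):
        diffs = self._diffs()
        oriented = orient_binary_pairs(diffs)
        row = oriented[oriented["outcome_diff"] == 1.0]
        assert "m1|f1" in set(
            oriented.loc[oriented["age_diff"] == 5.0, "pair_id"]
        )  # the (m1 case, f1 control) pair kept its orientation

    def test_idempotent(self):
        once = orient_binary_pairs(self._diffs())
        twice = orient_binary_pairs(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_invariant_to_initial_pair_order(self):
        cohort = _toy_cohort()
        pairs = _toy_pairs()
        flipped = pairs.rename(
            columns={"index_id": "partner_id", "partner_id": "index_id"}
        )
        a = orient_binary_pairs(
            compute_pair_differences(cohort, pairs, "pheno_case", ["g_1"], ["age"])
        )
        b = orient_binary_pairs(
            compute_pair_differences(cohort, flipped, "pheno_case", ["g_1"], ["age"])
        )
        cols = ["outcome_diff", "g_1_diff", "age_diff", "index_sex", "index_id"]
        a_sorted = a.sort_values("index_id")[cols].reset_index(drop=True)
        b_sorted = b.sort_values("index_id")[cols].reset_index(drop=True)
        pd.testing.assert_frame_equal(a_sorted, b_sorted)

    def test_nonbinary_outcome_rejected(self):
        diffs = self._diffs()
        diffs.loc[0, "outcome_diff"] = 0.5
        with pytest.raises(ValueError, match="binary"):
            orient_binary_pairs(diffs)


def _line_diffs(n=12, slope=2.0):
    x = np.arange(1.0, n + 1)
    return pd.DataFrame(
        {
            "pair_id": [f"p{i}" for i in range(n)],
            "outcome_diff": slope * x,
            "x_diff": x,
            "index_sex": 1.0,
            "partner_sex": 0.0,
        }
    )


def test_noiseless_linear_fit_recovers_slope_exactly():
    est = fit_pair_regression(_line_diffs(), ["x"], covariates=[])[0]
    assert est.beta == pytest.approx(2.0, abs=1e-12)
    assert est.se == pytest.approx(0.0, abs=1e-10)


def test_minimum_pair_count_enforced():
    with pytest.raises(ValueError, match="at least 10"):
        fit_pair_regression(_line_diffs(n=5), ["x"], covariates=[])


def test_constant_index_sex_is_pruned(caplog):
    import logging

    with caplog.at_level(logging.INFO, logger="wsplab.pair_models"):
        est = fit_pair_regression(_line_diffs(), ["x"])[0]
    assert est.beta == pytest.approx(2.0, abs=1e-12)
    assert any("constant covariate" in m for m in caplog.messages)


def test_rank_deficient_design_rejected():
    diffs = _line_diffs()
    diffs["x2_diff"] = 2.0 * diffs["x_diff"]
    with pytest.raises(ValueError, match="collinear"):
        fit_pair_regression(diffs, ["x"], covariates=["x2_diff"])


def test_slope_invariant_to_flipping_any_subset_of_pairs():
    rng = np.random.default_rng(17)
    n = 200
    x = rng.standard_normal(n)
    y = 0.5 * x + rng.standard_normal(n)
    diffs = pd.DataFrame(
        {"pair_id": [f"p{i}" for i in range(n)], "outcome_diff": y, "x_diff": x,
         "index_sex": 1.0, "partner_sex": 0.0}
    )
    base = fit_pair_regression(diffs, ["x"], covariates=[])[0]
    flip = rng.random(n) < 0.5
    flipped = diffs.copy()
    flipped.loc[flip, ["outcome_diff", "x_diff"]] *= -1
    alt = fit_pair_regression(flipped, ["x"], covariates=[])[0]
    assert alt.beta == pytest.approx(base.beta, abs=1e-12)
    assert alt.se == pytest.approx(base.se, abs=1e-12)


def test_random_pair_slope_matches_population_slope():
    # differencing independently paired individuals preserves the
    # population-level (confounded) slope in expectation
    rng = np.random.default_rng(23)
    n = 50_000
    E = rng.standard_normal(n)
    x = 0.5 * E + rng.standard_normal(n) * np.sqrt(0.75)
    y = 0.3 * x + 0.3 * E + rng.standard_normal(n)
    from scipy.stats import linregress

    pop = linregress(x, y)
    half = n // 2
    diffs = pd.DataFrame(
        {
            "pair_id": [f"p{i}" for i in range(half)],
            "outcome_diff": y[:half] - y[half:],
            "x_diff": x[:half] - x[half:],
            "index_sex": 1.0,
            "partner_sex": 0.0,
        }
    )
    est = fit_pair_regression(diffs, ["x"], covariates=[])[0]
    assert est.beta == pytest.approx(pop.slope, abs=3 * np.hypot(est.se, pop.stderr))


def test_null_logistic_is_calibrated():
    rng = np.random.default_rng(31)
    n = 5_000
    diffs = pd.DataFrame(
        {
            "pair_id": [f"p{i}" for i in range(n)],
            "outcome_diff": rng.integers(0, 2, n).astype(float),
            "g_diff": rng.integers(-2, 3, n).astype(float),
            "index_sex": rng.integers(0, 2, n).astype(float),
            "partner_sex": 0.0,
        }
    )
    est = fit_pair_regression(diffs, ["g"], family="logistic")[0]
    assert abs(est.beta / est.se) < 3.0


def test_logistic_requires_oriented_outcome():
    diffs = _line_diffs()
    with pytest.raises(ValueError, match="orient"):
        fit_pair_regression(diffs, ["x"], family="logistic")


class TestSummarizeRandomPairFits:
    @staticmethod
    def _est(variant, beta, se=0.1, n=100):
        return AssociationEstimate(variant, beta, se, n, "random_pair", "linear")

    def test_median_across_replicates(self):
        reps = [
            [self._est("g_1", 0.1)],
            [self._est("g_1", 0.2)],
            [self._est("g_1", 0.3)],
        ]
        (out,) = summarize_random_pair_fits(reps)
        assert out.beta == pytest.approx(0.2)
        assert out.model_label == "random_pair_median"

    def test_single_replicate_passthrough(self):
        (out,) = summarize_random_pair_fits([[self._est("g_1", 0.37, se=0.04)]])
        assert out.beta == pytest.approx(0.37)
        assert out.se == pytest.approx(0.04)

    def test_inconsistent_variant_sets_rejected(self):
        with pytest.raises(ValueError, match="variant sets"):
            summarize_random_pair_fits(
                [[self._est("g_1", 0.1)], [self._est("g_2", 0.1)]]
            )


def test_estimates_roundtrip(tmp_path):
    estimates = [
        AssociationEstimate("g_1", 0.25, 0.05, 500, "wsp", "linear"),
        AssociationEstimate("g_2", -0.1, 0.02, 500, "wsp", "linear"),
    ]
    path = tmp_path / "estimates.tsv"
    write_estimates(estimates, path)
    back = read_estimates(path)
    assert back == estimates
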