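"""GLM machinery: fits, family selection, calibration and marginal prediction."""

import numpy as np
import pandas as pd
import pytest

from ffrcea.regression import (
    DECISION_TERM,
    GlmSpec,
    fit_glm,
    fit_logistic,
    hosmer_lemeshow,
    marginal_predict,
    modified_park_test,
    partial_deviance_test,
    screen_covariates,
)


def _random_table(seed, n=200):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "y": rng.normal(5, 2, n),
            "x1": rng.normal(0, 1, n),
            "x2": rng.binomial(1, 0.4, n),
        }
    )


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_gaussian_identity_equals_least_squares(seed):
    tab = _random_table(seed)
    fitted = fit_glm(tab, GlmSpec("y", ["x1", "x2"]))
    X = np.column_stack([np.ones(len(tab)), tab["x1"], tab["x2"]])
    beta, *_ = np.linalg.lstsq(X, tab["y"].to_numpy(), rcond=None)
    np.testing.assert_allclose(fitted.params.to_numpy(), beta, rtol=1e-8)


@pytest.mark.parametrize("family,link", [("gaussian", "identity"), ("gamma", "log"), ("poisson", "log")])
def test_intercept_only_fits_sample_mean(family, link):
    rng = np.random.default_rng(3)
    tab = pd.DataFrame({"y": rng.gamma(4, 2, 500)})
    fitted = fit_glm(tab, GlmSpec("y", [], family=family, link=link))
    assert float(np.mean(fitted.fittedvalues)) == pytest.approx(tab["y"].mean(), rel=1e-6)


def test_gamma_log_coefficient_recovery():
    rng = np.random.default_rng(10)
    n = 5000
    x = rng.normal(0, 1, n)
    mu = np.exp(1.5 + 0.4 * x)
    shape = 5.0
    tab = pd.DataFrame({"y": rng.gamma(shape, mu / shape), "x": x})
    fitted = fit_glm(tab, GlmSpec("y", ["x"], family="gamma", link="log"))
    for name, truth in (("Intercept", 1.5), ("x", 0.4)):
        assert abs(fitted.params[name] - truth) < 3 * fitted.bse[name]


def test_missing_outcome_rejected():
    tab = _random_table(5)
    tab.loc[0, "y"] = np.nan
    with pytest.raises(ValueError, match="missing"):
        fit_glm(tab, GlmSpec("y", ["x1"]))


class TestModifiedPark:
    def test_gamma_variance_power_two(self):
        rng = np.random.default_rng(21)
        n = 5000
        x = rng.normal(0, 1, n)
        mu = np.exp(2.0 + 0.5 * x)
        tab = pd.DataFrame({"y": rng.gamma(2.0, mu / 2.0), "x": x})
        fitted = fit_glm(tab, GlmSpec("y", ["x"], family="gamma", link="log"))
        gamma, family = modified_park_test(fitted)
        assert family == "gamma"
        assert gamma == pytest.approx(2.0, abs=0.35)

    def test_homoskedastic_gaussian_power_zero(self):
        rng = np.random.default_rng(22)
        n = 5000
        x = rng.normal(0, 1, n)
        tab = pd.DataFrame({"y": 10 + 0.5 * x + rng.normal(0, 1, n), "x": x})
        fitted = fit_glm(tab, GlmSpec("y", ["x"]))
        gamma, family = modified_park_test(fitted)
        assert family == "gaussian"
        assert abs(gamma) < 0.5

    def test_degenerate_zero_residuals_error(self):
        # an exact fit leaves no residual variance to regress on
        tab = pd.DataFrame({"y": 2.0 + np.arange(1.0, 51.0), "x": np.arange(1.0, 51.0)})
        fitted = fit_glm(tab, GlmSpec("y", ["x"]))
        with pytest.raises(ValueError):
            modified_park_test(fitted)


class TestHosmerLemeshow:
    def test_df_is_g_minus_two(self):
        tab = _random_table(30, n=500)
        fitted = fit_glm(tab, GlmSpec("y", ["x1"]))
        _, df, _ = hosmer_lemeshow(fitted, g=10)
        assert df == 8

    def test_too_few_groups_rejected(self):
        tab = _random_table(31)
        fitted = fit_glm(tab, GlmSpec("y", ["x1"]))
        with pytest.raises(ValueError):
            hosmer_lemeshow(fitted, g=2)

    def test_calibrated_model_rejects_at_nominal_rate(self):
        # well-specified gaussian fits: rejection should be near 5%
        rejections = 0
        n_sims = 120
        for s in range(n_sims):
            tab = _random_table(1000 + s, n=400)
            tab["y"] = 1 + 2 * tab["x1"] + np.random.default_rng(s).normal(0, 1, 400)
            fitted = fit_glm(tab, GlmSpec("y", ["x1"]))
            if hosmer_lemeshow(fitted)[2] < 0.05:
                rejections += 1
        assert rejections / n_sims < 0.15

    def test_misspecified_link_is_rejected(self):
        # true log link fitted with identity: strong calibration failure
        rejections = 0
        for s in range(10):
            rng = np.random.default_rng(50 + s)
            x = rng.normal(0, 1, 2000)
            y = np.exp(1 + 0.8 * x) + rng.normal(0, 1, 2000)
            tab = pd.DataFrame({"y": y, "x": x})
            fitted = fit_glm(tab, GlmSpec("y", ["x"]))
            if hosmer_lemeshow(fitted)[2] < 0.05:
                rejections += 1
        assert rejections >= 8


class TestPartialDeviance:
    def test_identical_models_p_one(self):
        tab = _random_table(40)
        a = fit_glm(tab, GlmSpec("y", ["x1"]))
        b = fit_glm(tab, GlmSpec("y", ["x1"]))
        assert partial_deviance_test(a, b) == pytest.approx(1.0)

    def test_non_nested_rejected(self):
        tab = _random_table(41)
        a = fit_glm(tab, GlmSpec("y", ["x1"]))
        b = fit_glm(tab, GlmSpec("y", ["x2"]))
        with pytest.raises(ValueError, match="subset"):
            partial_deviance_test(a, b)

    def test_real_interaction_detected(self):
        rng = np.random.default_rng(60)
        n = 5000
        dec = rng.choice(["MT", "PCI", "CABG"], n, p=[0.2, 0.7, 0.1])
        mace = rng.binomial(1, 0.1, n)
        mu = np.exp(
            8.7 + 0.3 * (dec == "PCI") + 1.1 * (dec == "CABG")
            + 0.5 * mace + 0.4 * mace * (dec == "PCI") + 0.8 * mace * (dec == "CABG")
        )
        tab = pd.DataFrame({"cost": rng.gamma(4.0, mu / 4.0), "decision": dec, "mace": mace})
        nested = fit_glm(tab, GlmSpec("cost", [DECISION_TERM, "mace"], "gamma", "log"))
        full = fit_glm(tab, GlmSpec("cost", [f"{DECISION_TERM} * mace"], "gamma", "log"))
        assert partial_deviance_test(nested, full) < 0.001

    def test_noise_covariate_p_not_extreme(self):
        ps = []
        for s in range(40):
            tab = _random_table(100 + s, n=300)
            nested = fit_glm(tab, GlmSpec("y", ["x1"]))
            full = fit_glm(tab, GlmSpec("y", ["x1", "x2"]))
            ps.append(partial_deviance_test(nested, full))
        assert 0.3 < np.mean(ps) < 0.7  # approximately uniform p-values


class TestLogistic:
    def test_no_association_gives_or_one(self):
        tab = pd.DataFrame(
            {"mace": [0, 1] * 100, "group": [0, 0, 1, 1] * 50}
        )
        _, ors = fit_logistic(tab, GlmSpec("mace", ["group"]))
        assert ors.loc["group", "odds_ratio"] == pytest.approx(1.0, abs=1e-6)

    def test_saturated_fit_matches_cross_product_ratio(self):
        # 20/180 events vs 10/190: OR = (20*190)/(180*10) = 2.111
        mace = np.r_[np.ones(20), np.zeros(180), np.ones(10), np.zeros(190)]
        grp = np.r_[np.ones(200), np.zeros(200)]
        tab = pd.DataFrame({"mace": mace, "group": grp})
        _, ors = fit_logistic(tab, GlmSpec("mace", ["group"]))
        assert ors.loc["group", "odds_ratio"] == pytest.approx(20 * 190 / (180 * 10), rel=1e-5)

    def test_or_risk_round_trip_saturated(self):
        from ffrcea.decision_model import apply_or

        mace = np.r_[np.ones(20), np.zeros(180), np.ones(30), np.zeros(170)]
        grp = np.r_[np.ones(200), np.zeros(200)]
        tab = pd.DataFrame({"mace": mace, "group": grp})
        _, ors = fit_logistic(tab, GlmSpec("mace", ["group"]))
        baseline = 30 / 200
        assert apply_or(baseline, float(ors.loc["group", "odds_ratio"])) == pytest.approx(20 / 200)

    def test_cabg_or_within_printed_interval(self, complete_trial):
        from ffrcea.regression import MACE_SPEC_PREDICTORS

        tab = complete_trial.copy()
        tab["mace"] = tab["mace"].astype(int)
        _, ors = fit_logistic(tab, GlmSpec("mace", MACE_SPEC_PREDICTORS))
        or_cabg = float(ors.loc[f"{DECISION_TERM}[T.CABG]", "odds_ratio"])
        assert 0.98 < or_cabg < 14.62


class TestMarginalPredict:
    def test_single_predictor_recovers_group_mean(self):
        rng = np.random.default_rng(70)
        grp = rng.choice(["a", "b"], 300)
        y = 2.0 * (grp == "b") + rng.normal(0, 1, 300)
        tab = pd.DataFrame({"y": y, "grp": grp})
        fitted = fit_glm(tab, GlmSpec("y", ["grp"]))
        assert marginal_predict(fitted, tab, "grp", "b") == pytest.approx(y[grp == "b"].mean())

    def test_matches_row_wise_brute_force(self):
        tab = pd.DataFrame({"y": [1.0, 2.0, 3.0, 5.0], "x": [0.0, 1.0, 2.0, 3.0], "z": [1.0, 0.0, 1.0, 0.0]})
        fitted = fit_glm(tab, GlmSpec("y", ["x", "z"]))
        b = fitted.params
        hand = np.mean([b["Intercept"] + b["x"] * 2.0 + b["z"] * z for z in tab["z"]])
        assert marginal_predict(fitted, tab, "x", 2.0) == pytest.approx(hand)

    def test_unseen_level_rejected(self):
        tab = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0], "grp": ["a", "b", "a", "b"]})
        fitted = fit_glm(tab, GlmSpec("y", ["grp"]))
        with pytest.raises(ValueError, match="unseen|not seen"):
            marginal_predict(fitted, tab, "grp", "c")

    def test_frequency_weighted_levels_recover_overall_mean(self):
        rng = np.random.default_rng(71)
        grp = rng.choice(["a", "b", "c"], 500, p=[0.5, 0.3, 0.2])
        y = 1.0 + (grp == "b") * 2 + (grp == "c") * 3 + rng.normal(0, 1, 500)
        tab = pd.DataFrame({"y": y, "grp": grp})
        fitted = fit_glm(tab, GlmSpec("y", ["grp"]))
        freqs = tab["grp"].value_counts(normalize=True)
        weighted = sum(freqs[lev] * marginal_predict(fitted, tab, "grp", lev) for lev in freqs.index)
        assert weighted == pytest.approx(float(np.mean(fitted.fittedvalues)))


class TestScreening:
    def _table(self):
        rng = np.random.default_rng(80)
        n = 400
        rare = rng.binomial(1, 0.05, n)
        common = rng.binomial(1, 0.5, n)
        strong = rng.binomial(1, 0.4, n)
        y = 1.0 + 2.0 * strong + 2.0 * rare + rng.normal(0, 1, n)
        # a covariate exactly balanced against the outcome (zero association)
        null = np.tile([0, 1], n // 2)
        return pd.DataFrame({"y": y, "rare": rare, "common_null": null, "strong": strong, "common": common})

    def test_low_prevalence_excluded_despite_association(self):
        tab = self._table()
        kept = screen_covariates(tab, "y", ["rare", "strong"])
        assert "rare" not in kept and "strong" in kept

    def test_unassociated_covariate_excluded(self):
        tab = self._table()
        # y takes the same pair of values inside each level: association exactly 0
        tab["null2"] = np.tile([0, 0, 1, 1], len(tab) // 4)
        tab["y"] = np.tile([1.0, 2.0, 1.0, 2.0], len(tab) // 4)
        kept = screen_covariates(tab, "y", ["null2"])
        assert kept == []

    def test_empty_candidates(self, small_trial):
        assert screen_covariates(small_trial, "utility_0", []) == []

    def test_must_include_honoured(self):
        tab = self._table()
        kept = screen_covariates(tab, "y", ["rare", "strong"], must_include=("rare",))
        assert "rare" in kept
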