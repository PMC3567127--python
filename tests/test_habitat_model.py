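"""Logistic fitting, comparison statistics, and coefficient interpretation.

The in-package IRLS fitter and rank-based AUC are cross-checked against
independent routes: statsmodels maximum likelihood, exhaustive pairwise
AUC, and closed-form results for degenerate designs.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from springhab.habitat_model import (
    CollinearityError,
    FittedHabitatModel,
    ModelTerm,
    SeparationError,
    aic,
    akaike_weights,
    backward_eliminate,
    classification_accuracy,
    expand_terms,
    fit_logistic,
    hosmer_lemeshow,
    nagelkerke_r2,
    odds_ratios,
    parse_terms,
    quadratic_optimum,
    roc_auc,
)


def random_problem(seed, n=300, strength=3.0):
    rng = np.random.default_rng(seed)
    cov = pd.DataFrame({"DEP": rng.uniform(0, 0.8, n),
                        "VEL": rng.uniform(0, 0.6, n),
                        "SUB3": rng.choice([1, 2, 3], n)})
    eta = -1.0 + strength * cov.DEP.to_numpy() + 1.0 * (cov.SUB3 == 1)
    y = (rng.random(n) < expit(eta)).astype(float)
    return cov, y


class TestExpandTerms:
    def test_square_term(self):
        cov = pd.DataFrame({"DEP": [0.64]})
        design = expand_terms(cov, parse_terms(["DEP", "DEP^2"]))
        assert list(design.columns) == ["DEP", "DEP_2"]
        assert design.iloc[0].tolist() == pytest.approx([0.64, 0.4096])

    @pytest.mark.parametrize("sub3,expected", [(3, (0, 0)), (1, (1, 0)), (2, (0, 1))])
    def test_substrate_dummies_against_cobble_boulder(self, sub3, expected):
        cov = pd.DataFrame({"SUB3": [sub3]})
        design = expand_terms(cov, parse_terms(["SUB3"]))
        assert tuple(design.iloc[0]) == expected

    def test_log_of_nonpositive_rejected(self):
        cov = pd.DataFrame({"VEL": [0.0, 0.5]})
        with pytest.raises(ValueError, match="log"):
            expand_terms(cov, parse_terms(["log(VEL)"]))

    def test_cube_term(self):
        cov = pd.DataFrame({"DEP": [0.5]})
        design = expand_terms(cov, parse_terms(["DEP^3"]))
        assert design.iloc[0, 0] == pytest.approx(0.125)


class TestFitLogistic:
    def test_intercept_only_equals_prevalence_logit(self):
        y = np.r_[np.ones(141), np.zeros(309)]
        model = fit_logistic(pd.DataFrame(index=range(450)), y)
        assert model.coef["Constant"] == pytest.approx(np.log(141 / 309), abs=1e-8)
        assert model.n_params == 1

    def test_identical_labels_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(pd.DataFrame({"x": [1.0, 2.0]}), [1.0, 1.0])

    def test_matches_statsmodels_mle(self):
        import statsmodels.api as sm
        cov, y = random_problem(0)
        terms = parse_terms(["DEP", "DEP^2", "VEL", "SUB3"])
        design = expand_terms(cov, terms)
        model = fit_logistic(design, y, terms=terms)
        ref = sm.Logit(y, sm.add_constant(design, prepend=False)).fit(disp=0)
        np.testing.assert_allclose(model.coef.to_numpy(), ref.params.to_numpy(),
                                   atol=1e-8)
        np.testing.assert_allclose(model.se.to_numpy(), ref.bse.to_numpy(),
                                   atol=1e-8)
        assert model.minus_two_log_likelihood == pytest.approx(-2 * ref.llf)

    def test_parameter_recovery_within_3_se(self, scene, model2):
        # simulate occurrence from the reference dace model over the
        # synthetic channel and check the fit recovers every coefficient
        wet = scene.wet_mask()
        arrays = {v: scene[v].values[wet] for v in ("DEP", "VEL", "SUB3")}
        rng = np.random.default_rng(42)
        idx = rng.choice(len(arrays["DEP"]), size=2000, replace=False)
        cov = pd.DataFrame({k: v[idx] for k, v in arrays.items()})
        p = model2.predict_covariates(cov)
        y = (rng.random(2000) < p).astype(float)
        fit = fit_logistic(expand_terms(cov, model2.terms), y, terms=model2.terms)
        z = (fit.coef - model2.coef) / fit.se
        assert np.all(np.abs(z.to_numpy()) < 3.0)

    def test_complete_separation_detected(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = x.copy()
        with pytest.raises(SeparationError):
            fit_logistic(pd.DataFrame({"x": x}), y)

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, 50)
        design = pd.DataFrame({"a": x, "b": 2 * x})
        y = (rng.random(50) < expit(x)).astype(float)
        with pytest.raises(CollinearityError, match="a"):
            fit_logistic(design, y)

    def test_cross_variable_collinearity_flagged(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, 100)
        design = pd.DataFrame({"VEL": x, "FRD": x + rng.normal(0, 0.01, 100)})
        y = (rng.random(100) < expit(x - 0.5)).astype(float)
        with pytest.warns(UserWarning, match="collinearity"):
            fit_logistic(design, y)


class TestInformationCriteria:
    def test_aic_arithmetic(self):
        assert aic(407.461, 8) == pytest.approx(423.461)

    def test_weights_from_delta_aic_column(self):
        deltas = np.array([0.000, 1.780, 3.574, 3.576, 3.828, 4.455, 5.502,
                           79.326, 83.979, 100.532, 104.712, 112.353, 138.107])
        w = akaike_weights(deltas)  # weights are shift-invariant in AIC
        assert w[0] == pytest.approx(0.484, abs=5e-4)
        assert w[1] == pytest.approx(0.199, abs=5e-4)

    def test_single_model_weight_is_one(self):
        assert akaike_weights([410.0]) == pytest.approx([1.0])

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(min_value=100, max_value=1000), min_size=2, max_size=10))
    def test_weights_sum_to_one_and_decrease_with_aic(self, aics):
        w = akaike_weights(aics)
        assert w.sum() == pytest.approx(1.0)
        order = np.argsort(aics)
        assert np.all(np.diff(w[order]) <= 1e-12)


class TestNagelkerke:
    def test_null_model_scores_zero(self):
        assert nagelkerke_r2(500.0, 500.0, 450) == pytest.approx(0.0)

    def test_near_perfect_model_approaches_one(self):
        # deviance ~0 for a (near) perfectly predicted response
        assert nagelkerke_r2(1e-6, 600.0, 450) == pytest.approx(1.0, abs=1e-3)

    def test_small_dataset_matches_direct_formula(self):
        y = np.array([0, 0, 0, 1, 0, 1, 1, 1], dtype=float)
        x = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8])
        design = pd.DataFrame({"x": x})
        model = fit_logistic(design, y)
        null = fit_logistic(pd.DataFrame(index=range(8)), y)
        r2 = nagelkerke_r2(model.minus_two_log_likelihood,
                           null.minus_two_log_likelihood, 8)
        d1, d0 = model.minus_two_log_likelihood, null.minus_two_log_likelihood
        expected = (1 - np.exp((d1 - d0) / 8)) / (1 - np.exp(-d0 / 8))
        assert r2 == pytest.approx(expected, rel=1e-12)
        assert 0.0 <= r2 <= 1.0

    def test_zero_null_deviance_rejected(self):
        with pytest.raises(ValueError):
            nagelkerke_r2(0.0, 0.0, 10)


class TestHosmerLemeshow:
    def test_two_group_hand_example(self):
        # group A: p=0.2 x5, 2 observed; group B: p=0.8 x5, 3 observed
        p = np.r_[np.full(5, 0.2), np.full(5, 0.8)]
        y = np.r_[1, 1, 0, 0, 0, 1, 1, 1, 0, 0.0]
        res = hosmer_lemeshow(p, y, n_groups=2)
        # E1 = 1, 4; O1 = 2, 3 -> C = 1/1 + 1/4 + 1/4 + 1/1 = 2.5
        assert res.statistic == pytest.approx(2.5)
        assert res.n_groups == 2

    def test_fewer_observations_than_groups_rejected(self):
        with pytest.raises(ValueError):
            hosmer_lemeshow([0.5] * 5, [1, 0, 1, 0, 1], n_groups=10)

    def test_calibrated_model_gives_large_p_value(self):
        rng = np.random.default_rng(3)
        n = 2000
        x = rng.normal(0, 1, n)
        p_true = expit(-0.3 + x)
        y = (rng.random(n) < p_true).astype(float)
        model = fit_logistic(pd.DataFrame({"x": x}), y)
        res = hosmer_lemeshow(model.predict(pd.DataFrame({"x": x})), y)
        assert res.p_value > 0.05


class TestClassificationAndAuc:
    def test_all_correct_absences(self):
        oa, _ = classification_accuracy(np.zeros(10), np.zeros(10), cutpoint=0.3)
        assert oa == 100.0

    def test_overall_accuracy_counting(self):
        # 342 of 450 correct -> 76.0%
        y = np.r_[np.ones(141), np.zeros(309)]
        p = y.copy()
        p[:59] = 0.0   # 59 presences misclassified
        p[141:190] = 1.0  # 49 absences misclassified
        oa, table = classification_accuracy(p, y)
        assert oa == pytest.approx(100 * 342 / 450)
        assert table.loc["observed_presence", "predicted_presence"] == 82

    def test_cutpoint_one_classifies_everything_absent(self):
        y = np.r_[np.ones(5), np.zeros(5)]
        p = np.linspace(0, 1, 10)
        oa, table = classification_accuracy(p, y, cutpoint=1.0)
        assert table["predicted_presence"].sum() == 0

    def test_perfect_separation_auc_one(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_auc_half(self):
        assert roc_auc([0.5] * 10, [1] * 4 + [0] * 6) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.2, 0.4], [1, 1])

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(min_value=0, max_value=10_000), st.integers(min_value=4, max_value=50))
    def test_rank_auc_equals_exhaustive_pairwise(self, seed, n):
        rng = np.random.default_rng(seed)
        p = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # ties likely
        y = rng.integers(0, 2, size=n)
        if y.sum() in (0, n):
            y[0], y[-1] = 0, 1
        pairs = [(a, b) for a in p[y == 1] for b in p[y == 0]]
        brute = np.mean([1.0 if a > b else 0.5 if a == b else 0.0 for a, b in pairs])
        assert roc_auc(p, y) == pytest.approx(brute, rel=1e-12)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(4)
        p = rng.random(200)
        y = rng.integers(0, 2, 200)
        assert roc_auc(p, y) == pytest.approx(roc_auc_score(y, p), rel=1e-12)


class TestBackwardElimination:
    def test_truly_null_velocity_dropped_before_depth(self):
        dropped = 0
        for rep in range(50):
            rng = np.random.default_rng(2000 + rep)
            n = 400
            cov = pd.DataFrame({"DEP": rng.uniform(0, 0.8, n),
                                "VEL": rng.uniform(0, 0.6, n)})
            eta = -1.5 + 4.0 * cov.DEP.to_numpy()
            y = (rng.random(n) < expit(eta)).astype(float)
            comp = backward_eliminate(cov, y, parse_terms(["DEP", "VEL"]))
            best_vars = comp.table.iloc[0]["variables"]
            dropped += ("DEP" in best_vars) and ("VEL" not in best_vars)
        assert dropped / 50 > 0.9

    def test_single_term_model_returned_unchanged(self):
        cov, y = random_problem(5)
        comp = backward_eliminate(cov, y, parse_terms(["DEP"]))
        assert comp.best.column_names == ["DEP"]

    def test_table_sorted_by_aic_with_unit_weight_sum(self, samples):
        terms = parse_terms(["DEP", "DEP^2", "VEL", "VEL^2", "SUB3"])
        comp = backward_eliminate(samples.covariates(), samples.labels, terms)
        table = comp.table
        assert (table["AIC"].diff().dropna() >= 0).all()
        assert table["w"].sum() == pytest.approx(1.0)
        assert table["dAIC"].min() == 0.0
        assert (table["OA"].between(0, 100)).all()
        assert (table["AUC"].between(0, 1)).all()


class TestInterpretation:
    def test_substrate_odds_ratios(self, model2):
        ors = odds_ratios(model2)
        # sandy substrate ~3x, gravel ~2x the odds of cobble/boulder
        assert round(ors.loc["SUB3_1", "odds_ratio"]) == 3
        assert round(ors.loc["SUB3_2", "odds_ratio"]) == 2
        assert ors.loc["SUB3_1", "odds_ratio"] == pytest.approx(np.exp(1.126))

    def test_zero_coefficient_gives_unit_odds(self):
        model = FittedHabitatModel.from_coefficients(
            (ModelTerm("DEP"),), {"DEP": 0.0, "Constant": 0.0})
        assert odds_ratios(model).loc["DEP", "odds_ratio"] == 1.0

    def test_ci_uses_1_96_se(self, model2):
        ors = odds_ratios(model2)
        assert ors.loc["DEP", "ci_high"] == pytest.approx(np.exp(13.935 + 1.96 * 4.426))

    @pytest.mark.parametrize("which,var,expected", [
        ("m2", "DEP", 0.64), ("m1", "DEP", 0.71),
        ("m2", "VEL", 0.14), ("m1", "FRD", 0.10),
    ])
    def test_quadratic_optima_match_published_preferences(self, which, var,
                                                          expected, model1, model2):
        model = model2 if which == "m2" else model1
        ndigits = 1 if var == "FRD" else 2
        assert round(quadratic_optimum(model, var), ndigits) == pytest.approx(expected)

    def test_upward_opening_quadratic_has_no_maximum(self):
        model = FittedHabitatModel.from_coefficients(
            (ModelTerm("DEP"), ModelTerm("DEP", "square")),
            {"DEP": 1.0, "DEP_2": 2.0, "Constant": 0.0})
        with pytest.raises(ValueError, match="no interior maximum"):
            quadratic_optimum(model, "DEP")

    def test_missing_squared_term_rejected(self, model2):
        with pytest.raises(ValueError, match="lacks"):
            quadratic_optimum(model2, "TMP")
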