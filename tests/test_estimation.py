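"""Estimation battery: designs, OLS, censored-normal Tobit, two-part, stepwise."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from epicmap.estimation import (
    DesignSpec,
    EstimationError,
    ForwardStepwise,
    OLSRegressor,
    SingularityError,
    TobitRegressor,
    TwoPartRegressor,
    build_design_matrix,
    fit_ols,
    fit_tobit,
    fit_two_part,
    predict_tobit,
    stepwise_forward,
    to_mapping_model,
)
from epicmap.mapping import builtin_full_model_6i
from epicmap.simulate import LinearTruthParams, generate_linear_truth


def _censored_loglik(beta0, beta1, sigma, x, y, upper=1.0):
    """Independent censored-normal log-likelihood (direct formula)."""
    mu = beta0 + beta1 * x
    cens = y == upper
    ll = np.sum(scipy.stats.norm.logpdf(y[~cens], loc=mu[~cens], scale=sigma))
    ll += np.sum(scipy.stats.norm.logsf(upper, loc=mu[cens], scale=sigma))
    return ll


class TestDesignSpec:
    def test_group1_gives_four_score_columns(self):
        design = DesignSpec(group=1)
        names = [name for name, _ in design.columns()]
        assert names == ["epic_urinary", "epic_bowel", "epic_sexual", "epic_hormonal"]

    def test_group6_cubic_age_zubrod_interactions_matches_published_regressors(self):
        """The group-6 full design with a cubic in age and score x Zubrod
        products spans exactly the 26 regressors of the published full model."""
        spec = DesignSpec(group=6, age_powers=(1, 2, 3), interactions=("zubrod",), label="6i")
        design_signatures = {tuple(sorted(v)) for _, v in spec.columns()}
        model_signatures = {t.signature for t in builtin_full_model_6i().terms}
        assert len(spec.columns()) == 26
        assert design_signatures == model_signatures

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(group=0),
            dict(group=1, interactions=("zubrod",)),
            dict(group=2, interactions=("race",)),
            dict(group=4, interactions=("zubrod",)),
            dict(group=1, score_powers=()),
            dict(group=1, score_powers=(4,)),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DesignSpec(**kwargs)


class TestBuildDesignMatrix:
    def test_complete_case_exclusion_counted(self, cohort_565):
        df = cohort_565.copy()
        df.loc[df.index[3], "epic_bb"] = np.nan
        design = build_design_matrix(df, DesignSpec(group=2))
        assert design.n_dropped == 1
        assert design.n == len(df) - 1
        assert df.index[3] in design.dropped_index

    def test_polynomials_and_interactions_are_literal(self, cohort_565):
        spec = DesignSpec(group=5, age_powers=(1, 2), interactions=("zubrod",))
        design = build_design_matrix(cohort_565, spec)
        X = design.X
        np.testing.assert_allclose(X["age_p2"], cohort_565["age"] ** 2)
        np.testing.assert_allclose(
            X["epic_urinary_x_zubrod"], cohort_565["epic_urinary"] * cohort_565["zubrod"]
        )

    def test_zero_usable_records_is_estimation_error(self, cohort_565):
        df = cohort_565.copy()
        df["epic_urinary"] = np.nan
        with pytest.raises(EstimationError, match="usable"):
            build_design_matrix(df, DesignSpec(group=1))


class TestOLS:
    def test_matches_normal_equations_on_random_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n, p = rng.integers(8, 40), rng.integers(1, 5)
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            est = OLSRegressor().fit(X, y)
            X1 = np.column_stack([np.ones(n), X])
            beta = np.linalg.solve(X1.T @ X1, X1.T @ y)
            np.testing.assert_allclose(
                np.r_[est.intercept_, est.coef_], beta, rtol=1e-8, atol=1e-10
            )

    def test_three_point_hand_least_squares(self):
        # x = 0,1,2; y = 1,2,4 -> slope 1.5, intercept 2.3333.. - 1.5 = 5/6
        est = OLSRegressor().fit(np.array([[0.0], [1.0], [2.0]]), np.array([1.0, 2.0, 4.0]))
        assert est.coef_[0] == pytest.approx(1.5)
        assert est.intercept_ == pytest.approx(5.0 / 6.0)

    def test_exact_linear_data_interpolates(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 2))
        y = 0.3 + X @ np.array([1.0, -2.0])
        est = OLSRegressor().fit(X, y)
        np.testing.assert_allclose(est.predict(X), y, atol=1e-10)

    def test_duplicate_column_is_singularity_error_naming_columns(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        with pytest.raises(SingularityError, match="collinear"):
            OLSRegressor().fit(X, [1.0, 2, 3, 4])

    def test_nesting_monotonicity(self):
        """Adding a regressor never increases the training residual sum of squares."""
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        y = rng.normal(size=60)
        ssr = []
        for k in range(1, 5):
            est = OLSRegressor().fit(X.iloc[:, :k], y)
            ssr.append(float(np.sum((y - est.predict(X.iloc[:, :k])) ** 2)))
        assert all(s2 <= s1 + 1e-10 for s1, s2 in zip(ssr, ssr[1:]))


class TestTobit:
    def test_censoring_free_reduction_to_ols_ml(self):
        table, _ = generate_linear_truth(LinearTruthParams(censor=False), n=400, seed=5)
        X, y = table[["x1", "x2", "x3"]], table["y"]
        tob = TobitRegressor().fit(X, y)
        ols = OLSRegressor().fit(X, y)
        np.testing.assert_allclose(tob.coef_, ols.coef_, atol=1e-6)
        assert tob.intercept_ == pytest.approx(ols.intercept_, abs=1e-6)
        assert tob.sigma_ == pytest.approx(ols.sigma_, abs=1e-6)  # ML (RMS) scale

    def test_beats_dense_grid_oracle_on_tiny_dataset(self):
        """Optimizer log-likelihood >= every point of a dense 3-D grid over
        (beta0, beta1, sigma) on a 6-observation, 2-censored example."""
        x = np.array([-1.0, -0.5, 0.0, 0.5, 1.0, 1.5])
        y = np.array([0.55, 0.70, 0.85, 0.90, 1.00, 1.00])
        est = TobitRegressor().fit(x[:, None], y)
        assert est.converged_
        grid_best = -np.inf
        for b0 in np.linspace(0.3, 1.4, 45):
            for b1 in np.linspace(-0.3, 0.9, 45):
                for sigma in np.geomspace(0.02, 0.6, 45):
                    grid_best = max(grid_best, _censored_loglik(b0, b1, sigma, x, y))
        assert est.loglik_ >= grid_best - 1e-9

    def test_loglik_dominates_random_parameter_draws(self):
        table, _ = generate_linear_truth(n=300, seed=9)
        X, y = table[["x1", "x2", "x3"]].to_numpy(), table["y"].to_numpy()
        est = TobitRegressor().fit(X, y)
        rng = np.random.default_rng(17)
        theta_hat = np.r_[est.intercept_, est.coef_, est.sigma_]
        for _ in range(1000):
            theta = theta_hat + rng.normal(0, 0.05, size=theta_hat.size)
            sigma = abs(theta[-1]) + 1e-6
            mu = theta[0] + X @ theta[1:-1]
            cens = y == 1.0
            ll = np.sum(scipy.stats.norm.logpdf(y[~cens], mu[~cens], sigma))
            ll += np.sum(scipy.stats.norm.logsf(1.0, mu[cens], sigma))
            assert est.loglik_ >= ll - 1e-9

    def test_parameter_recovery_under_heavy_censoring(self):
        params = LinearTruthParams()
        table, truth = generate_linear_truth(params, n=2000, seed=123)
        assert 0.40 <= truth["censored_fraction"] <= 0.55
        X, y = table[["x1", "x2", "x3"]], table["y"]
        est = TobitRegressor().fit(X, y)
        estimates = np.r_[est.intercept_, est.coef_]
        true_values = np.r_[params.intercept, params.beta]
        ses = est.bse_.to_numpy()
        assert np.all(np.abs(estimates - true_values) <= 3 * ses)
        assert est.sigma_ == pytest.approx(params.sigma, rel=0.05)

    def test_all_censored_is_estimation_error(self):
        with pytest.raises(EstimationError, match="censored"):
            TobitRegressor().fit(np.arange(6.0)[:, None], np.ones(6))

    @pytest.mark.parametrize(
        "latent, policy, expected",
        [(0.9, "truncate_at_1", 0.9), (1.2, "truncate_at_1", 1.0), (1.2, "latent", 1.2)],
    )
    def test_prediction_policies(self, latent, policy, expected):
        table, _ = generate_linear_truth(n=200, seed=2)
        est = TobitRegressor().fit(table[["x1", "x2", "x3"]], table["y"])
        # force a known latent mean through a synthetic fit copy
        est.intercept_, est.coef_ = latent, np.zeros(3)
        pred = est.predict(pd.DataFrame({"x1": [0.0], "x2": [0.0], "x3": [0.0]}), policy=policy)
        assert pred[0] == pytest.approx(expected)

    def test_censored_expectation_matches_monte_carlo(self):
        """Closed-form E[min(Y*, 1)] at latent mean 1, sigma 0.1 vs a
        10^6-draw Monte-Carlo oracle."""
        table, _ = generate_linear_truth(n=200, seed=2)
        est = TobitRegressor().fit(table[["x1", "x2", "x3"]], table["y"])
        est.intercept_, est.coef_, est.sigma_ = 1.0, np.zeros(3), 0.1
        closed = est.predict(
            pd.DataFrame({"x1": [0.0], "x2": [0.0], "x3": [0.0]}), policy="censored_expectation"
        )[0]
        rng = np.random.default_rng(99)
        mc = np.minimum(rng.normal(1.0, 0.1, 1_000_000), 1.0).mean()
        assert closed == pytest.approx(mc, abs=4 * 0.06 / 1000)  # 4 MC standard errors

    def test_unknown_policy_is_usage_error(self):
        table, _ = generate_linear_truth(n=100, seed=2)
        est = TobitRegressor().fit(table[["x1", "x2", "x3"]], table["y"])
        with pytest.raises(ValueError, match="policy"):
            est.predict(table[["x1", "x2", "x3"]], policy="clamp")

    def test_fitresult_wrapper_round_trip(self):
        table, _ = generate_linear_truth(n=300, seed=4)
        X = table[["x1", "x2", "x3"]]
        fit = fit_tobit(X, table["y"])
        assert fit.converged and fit.scale_sigma > 0
        direct = TobitRegressor().fit(X, table["y"]).predict(X)
        np.testing.assert_allclose(predict_tobit(fit, X), direct, atol=1e-10)


class TestTwoPart:
    def test_no_ceiling_reduces_exactly_to_ols(self):
        table, _ = generate_linear_truth(LinearTruthParams(intercept=0.0, censor=False), n=200, seed=6)
        X, y = table[["x1", "x2", "x3"]], table["y"]
        assert not np.any(y.to_numpy() == 1.0)
        tp = TwoPartRegressor().fit(X, y)
        ols = OLSRegressor().fit(X, y)
        np.testing.assert_allclose(tp.predict(X), ols.predict(X), atol=1e-10)

    def test_combination_rule(self):
        """Combined prediction is p * ceiling + (1 - p) * part-2 prediction."""
        table, _ = generate_linear_truth(n=300, seed=8)
        X, y = table[["x1", "x2", "x3"]], table["y"]
        tp = TwoPartRegressor().fit(X, y)
        p = tp.predict_ceiling_probability(X)
        y2 = tp.predict_below_ceiling(X)
        np.testing.assert_allclose(tp.predict(X), p + (1 - p) * y2, atol=1e-12)

    def test_combined_prediction_bounded_by_ceiling(self):
        table, _ = generate_linear_truth(n=300, seed=8)
        X, y = table[["x1", "x2", "x3"]], table["y"]
        tp = TwoPartRegressor().fit(X, y)
        y2 = tp.predict_below_ceiling(X)
        combined = tp.predict(X)
        assert np.all(combined <= np.maximum(y2, 1.0) + 1e-12)
        assert np.all(combined >= np.minimum(y2, 1.0) - 1e-12)

    def test_perfect_separation_flagged_not_raised(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=80)
        y = np.where(x > 0, 1.0, 0.5 + 0.1 * rng.random(80))
        tp = TwoPartRegressor().fit(x[:, None], y)
        assert tp.part1_converged_ is False
        assert tp.converged_ is False

    def test_all_ceiling_is_estimation_error_naming_part(self):
        with pytest.raises(EstimationError, match="part 2"):
            TwoPartRegressor().fit(np.arange(10.0)[:, None], np.ones(10))

    def test_two_distinct_values_required_below_ceiling(self):
        y = np.array([1.0, 1.0, 0.5, 0.5, 0.5, 1.0])
        with pytest.raises(EstimationError, match="part 2"):
            TwoPartRegressor().fit(np.arange(6.0)[:, None], y)

    def test_fitresult_carries_both_parts(self):
        table, _ = generate_linear_truth(n=300, seed=8)
        fit = fit_two_part(table[["x1", "x2", "x3"]], table["y"])
        assert fit.part1_coefficients is not None
        assert set(fit.coefficients) == {"const", "x1", "x2", "x3"}


class TestForwardStepwise:
    def test_signal_regressor_selected_noise_mostly_excluded(self):
        """y depends only on A among {A, B}: A is always selected; pure-noise
        B enters at roughly the 0.25 entry-threshold false-inclusion rate."""
        a_selected, b_selected = 0, 0
        rng = np.random.default_rng(21)
        for _ in range(200):
            n = 300
            X = pd.DataFrame({"A": rng.normal(size=n), "B": rng.normal(size=n)})
            y = 1.0 + 0.5 * X["A"] + rng.normal(0, 0.5, n)
            fs = ForwardStepwise().fit(X, y)
            a_selected += "A" in fs.selected_
            b_selected += "B" in fs.selected_
        assert a_selected == 200
        assert b_selected / 200 <= 0.35

    def test_empty_candidate_pool_gives_intercept_only(self):
        y = np.array([0.5, 0.7, 0.9, 1.1])
        fs = ForwardStepwise().fit(pd.DataFrame(index=range(4)), y)
        assert fs.selected_ == []
        np.testing.assert_allclose(fs.predict(pd.DataFrame(index=range(4))), np.mean(y))

    def test_sle_one_admits_every_candidate(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        y = rng.normal(size=50)
        fs = ForwardStepwise(sle=1.0, slstay=1.0).fit(X, y)
        assert set(fs.selected_) == set("abcd")

    def test_weak_hierarchy_orders_parents_before_product(self):
        rng = np.random.default_rng(13)
        n = 400
        a, b = rng.normal(size=n), rng.normal(size=n)
        X = pd.DataFrame({"a": a, "b": b, "a_x_b": a * b})
        X.attrs["parents"] = {"a_x_b": ("a", "b")}
        y = 2.0 * a * b + rng.normal(0, 0.5, n)
        fs = ForwardStepwise(hierarchy=True).fit(X, y)
        if "a_x_b" in fs.selected_:
            assert {"a", "b"} <= set(fs.selected_)
            assert fs.selected_.index("a_x_b") > max(
                fs.selected_.index("a"), fs.selected_.index("b")
            )
        no_hier = ForwardStepwise(hierarchy=False).fit(X, y)
        assert no_hier.selected_[0] == "a_x_b"

    @pytest.mark.parametrize("form", ["ols", "tobit", "two_part"])
    def test_wrapper_returns_selection(self, cohort_565, form):
        from epicmap.estimation import build_design_matrix

        design = build_design_matrix(cohort_565, DesignSpec(group=1))
        fit, selected = stepwise_forward(design.X, design.y, form=form)
        assert fit.converged
        assert selected  # hormonal domain carries strong signal in the cohort
        assert "epic_hormonal" in selected


class TestMappingExport:
    def test_export_round_trips_into_prediction(self, cohort_565):
        design = build_design_matrix(cohort_565, DesignSpec(group=1))
        est = OLSRegressor().fit(design.X, design.y)
        model = to_mapping_model(
            est, name="g1", group=1, form="ols", variables=design.X.attrs["variables"]
        )
        np.testing.assert_allclose(model.predict(cohort_565), est.predict(design.X), atol=1e-12)
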