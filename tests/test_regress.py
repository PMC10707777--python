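"""Median and logistic regression with backward AIC block selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linprog

from chronoprof import LogisticModel, MedianRegression, ModelSpec, Term, \
    backward_select
from chronoprof.regress import design_matrix, median_fit_lp, pinball_loss


def dual_lp_objective(X, y, tau=0.5):
    """Independent check via LP duality: max yᵀν s.t. Xᵀν = 0, ν ∈ [τ−1, τ].

    Strong duality makes the optimum equal the minimal pinball loss of the
    primal fit, through a formulation the implementation never touches.
    """
    n = X.shape[0]
    res = linprog(-y, A_eq=X.T, b_eq=np.zeros(X.shape[1]),
                  bounds=[(tau - 1, tau)] * n, method="highs")
    assert res.success
    return -res.fun


class TestMedianRegression:
    def test_intercept_only_is_sample_median(self, rng):
        y = rng.normal(2.0, 1.0, 41)          # odd n: unique median
        beta = median_fit_lp(np.ones((41, 1)), y)
        assert beta[0] == pytest.approx(np.median(y), abs=1e-10)

    def test_exact_affine_data_recovered_with_zero_loss(self, rng):
        x = rng.normal(0, 1, 30)
        y = 1.5 + 2.0 * x
        X = np.column_stack([np.ones(30), x])
        beta = median_fit_lp(X, y)
        assert np.allclose(beta, [1.5, 2.0], atol=1e-9)
        assert pinball_loss(y - X @ beta) == pytest.approx(0, abs=1e-9)

    def test_objective_matches_dual_lp_oracle_on_random_instances(self):
        for seed in range(25):
            r = np.random.default_rng(seed)
            n = int(r.integers(10, 41))
            p = int(r.integers(1, 5))
            X = np.column_stack([np.ones(n), r.normal(size=(n, p - 1))]) \
                if p > 1 else np.ones((n, 1))
            y = r.normal(size=n)
            beta = median_fit_lp(X, y)
            assert pinball_loss(y - X @ beta) == pytest.approx(
                dual_lp_objective(X, y), abs=1e-8)

    def test_agrees_with_statsmodels_quantreg(self, rng):
        import statsmodels.api as sm
        x = rng.normal(0, 1, 200)
        y = 1.0 + 0.8 * x + rng.standard_t(3, 200)
        X = np.column_stack([np.ones(200), x])
        beta = median_fit_lp(X, y)
        qr = sm.QuantReg(y, X).fit(q=0.5)
        assert pinball_loss(y - X @ beta) <= pinball_loss(y - X @ qr.params) + 1e-8
        assert np.allclose(beta, qr.params, atol=1e-3)

    def test_pseudo_r1_bounds_and_monotonicity(self, rng):
        n = 120
        x1 = rng.normal(0, 1, n)
        x2 = rng.normal(0, 1, n)
        y = 2 + x1 + rng.normal(0, 1, n)
        df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        f0 = MedianRegression.from_dataframe(
            df, ModelSpec("y", "median", [])).fit()
        f1 = MedianRegression.from_dataframe(
            df, ModelSpec("y", "median", [Term("x1")])).fit()
        f2 = MedianRegression.from_dataframe(
            df, ModelSpec("y", "median", [Term("x1"), Term("x2")])).fit()
        assert f0.pseudo_r1 == pytest.approx(0.0, abs=1e-12)
        assert 0 <= f1.pseudo_r1 <= f2.pseudo_r1 <= 1

    def test_exact_fit_gives_r1_of_one(self, rng):
        x = rng.normal(0, 1, 50)
        df = pd.DataFrame({"y": 3 * x - 1, "x": x})
        fit = MedianRegression.from_dataframe(
            df, ModelSpec("y", "median", [Term("x")])).fit()
        assert fit.pseudo_r1 == pytest.approx(1.0, abs=1e-9)

    def test_bootstrap_cis_bracket_estimates(self, rng):
        x = rng.normal(0, 1, 150)
        df = pd.DataFrame({"y": 1 + 2 * x + rng.normal(0, 1, 150), "x": x})
        fit = MedianRegression.from_dataframe(
            df, ModelSpec("y", "median", [Term("x")])).fit(
            boot_ci=True, n_boot=199, seed=0)
        assert (fit.conf_int["lo95"] <= fit.params).all()
        assert (fit.params <= fit.conf_int["hi95"]).all()

    def test_rank_deficient_design_names_columns(self, rng):
        x = rng.normal(0, 1, 50)
        df = pd.DataFrame({"y": rng.normal(0, 1, 50), "x": x, "x2": 2 * x})
        with pytest.raises(ValueError, match="collinear"):
            MedianRegression.from_dataframe(
                df, ModelSpec("y", "median", [Term("x"), Term("x2")]))


class TestLogistic:
    def test_two_by_two_odds_ratio_cross_product(self):
        # a=10 exposed cases, b=20 exposed controls, c=30, d=40
        y = np.repeat([1, 0, 1, 0], [10, 20, 30, 40])
        x = np.repeat([1, 1, 0, 0], [10, 20, 30, 40])
        df = pd.DataFrame({"y": y, "x": x})
        fit = LogisticModel.from_dataframe(
            df, ModelSpec("y", "logistic", [Term("x")])).fit()
        assert np.exp(fit.params["x"]) == pytest.approx((10 * 40) / (20 * 30),
                                                        rel=1e-6)

    def test_balanced_no_association_gives_unit_or(self):
        y = np.tile([0, 1], 40)
        x = np.repeat([0, 1], 40)
        df = pd.DataFrame({"y": y, "x": x})
        fit = LogisticModel.from_dataframe(
            df, ModelSpec("y", "logistic", [Term("x")])).fit()
        assert np.exp(fit.params["x"]) == pytest.approx(1.0, abs=1e-8)

    def test_aic_matches_independent_likelihood_evaluation(self, rng):
        x = rng.normal(0, 1, 300)
        p = 1 / (1 + np.exp(-(0.3 + 0.8 * x)))
        y = (rng.random(300) < p).astype(float)
        df = pd.DataFrame({"y": y, "x": x})
        fit = LogisticModel.from_dataframe(
            df, ModelSpec("y", "logistic", [Term("x")])).fit()
        X = np.column_stack([np.ones(300), x])
        eta = X @ fit.params.to_numpy()
        phat = 1 / (1 + np.exp(-eta))
        ll = float(np.sum(y * np.log(phat) + (1 - y) * np.log(1 - phat)))
        assert fit.aic == pytest.approx(2 * 2 - 2 * ll, rel=1e-8)

    def test_odds_ratio_table_exponentiates_intervals(self, rng):
        x = rng.normal(0, 1, 200)
        y = (rng.random(200) < 0.5).astype(float)
        fit = LogisticModel.from_dataframe(
            pd.DataFrame({"y": y, "x": x}),
            ModelSpec("y", "logistic", [Term("x")])).fit()
        ors = fit.odds_ratios
        assert (ors["lo95"] <= ors["OR"]).all() and (ors["OR"] <= ors["hi95"]).all()
        assert (ors["OR"] > 0).all()


class TestDesignAndSelection:
    def test_factor_blocks_use_reference_coding(self):
        df = pd.DataFrame({"edu": ["middle", "high", "degree+", "middle"]})
        X, blocks = design_matrix(
            df, [Term("edu", True, "middle", ("middle", "high", "degree+"))])
        assert blocks["edu"] == ["edu[high]", "edu[degree+]"]
        assert X["edu[high]"].tolist() == [0, 1, 0, 0]

    def test_noise_only_predictors_mostly_dropped(self):
        # Laplace outcome noise: the asymmetric-Laplace working likelihood
        # behind the quantile AIC is then the true likelihood, so the
        # selection operates at its nominal calibration
        kept = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            n = 400
            df = pd.DataFrame({"y": 2.0 + r.laplace(0, 1, n),
                               "n1": r.normal(0, 1, n),
                               "n2": r.normal(0, 1, n)})
            spec = ModelSpec("y", "median", [Term("n1"), Term("n2")])
            fit = backward_select(spec, df, boot_ci=False)
            kept += len(fit.params) > 1
        assert kept <= 9     # intercept-only selected in the majority

    def test_strong_predictor_always_retained(self):
        for seed in range(5):
            r = np.random.default_rng(seed)
            x = r.normal(0, 1, 200)
            df = pd.DataFrame({"y": 3 * x + r.normal(0, 0.5, 200), "x": x,
                               "noise": r.normal(0, 1, 200)})
            spec = ModelSpec("y", "median", [Term("x"), Term("noise")])
            fit = backward_select(spec, df, boot_ci=False)
            assert "x" in fit.params.index

    def test_trace_aic_strictly_decreasing(self, rng):
        df = pd.DataFrame({"y": rng.normal(0, 1, 100),
                           "a": rng.normal(0, 1, 100),
                           "b": rng.normal(0, 1, 100)})
        fit = backward_select(ModelSpec("y", "median", [Term("a"), Term("b")]),
                              df, boot_ci=False)
        aics = [s["aic"] for s in fit.selection_trace]
        assert all(x > y for x, y in zip(aics, aics[1:]))

    def test_noise_column_raises_aic_at_large_n(self):
        hits = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            n = 1000
            x = r.normal(0, 1, n)
            # Laplace noise: quantile AIC operates at nominal calibration
            y = 1 + x + r.laplace(0, 1, n)
            noise = r.normal(0, 1, n)
            df = pd.DataFrame({"y": y, "x": x, "noise": noise})
            f1 = MedianRegression.from_dataframe(
                df, ModelSpec("y", "median", [Term("x")])).fit()
            f2 = MedianRegression.from_dataframe(
                df, ModelSpec("y", "median", [Term("x"), Term("noise")])).fit()
            hits += f2.aic > f1.aic
        assert hits >= 40

    def test_row_order_invariance(self, rng):
        x = rng.normal(0, 1, 80)
        df = pd.DataFrame({"y": 1 + x + rng.normal(0, 1, 80), "x": x})
        spec = ModelSpec("y", "median", [Term("x")])
        f1 = MedianRegression.from_dataframe(df, spec).fit()
        f2 = MedianRegression.from_dataframe(
            df.sample(frac=1, random_state=1), spec).fit()
        assert np.allclose(f1.params, f2.params, atol=1e-8)
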