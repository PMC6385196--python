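"""NB2 count-model fitting, screening, VIF and the delta model search."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats

from hrvidh import (
    NBFit,
    fit_negative_binomial,
    linear_predictor,
    model_search,
    univariate_screen,
    vif,
    wald_exp_coefficients,
)


def poisson_mle_oracle(y, X):
    """Independent Poisson ML oracle via direct likelihood maximisation."""
    Xc = np.column_stack([np.ones(len(y)), np.asarray(X, float)])

    def nll(beta):
        eta = Xc @ beta
        return -(y @ eta - np.exp(eta).sum())

    res = optimize.minimize(nll, np.zeros(Xc.shape[1]), method="BFGS")
    return res.x


def nb2_loglike(y, mu, alpha):
    """NB2 log-likelihood oracle via the gamma-function form."""
    size = 1.0 / alpha
    prob = size / (size + mu)
    return float(np.sum(stats.nbinom.logpmf(y, size, prob)))


def simulate_nb(rng, n, beta, alpha):
    x = rng.normal(0, 1, size=n)
    mu = np.exp(beta[0] + beta[1] * x)
    lam = rng.gamma(1 / alpha, alpha * mu) if alpha > 1e-10 else mu
    return rng.poisson(lam), pd.DataFrame({"x": x})


class TestNBFit:
    def test_intercept_only_recovers_log_mean(self):
        y = np.full(40, 3)
        fit = fit_negative_binomial(y, pd.DataFrame(index=range(40)))
        assert fit.params["const"] == pytest.approx(math.log(3.0), abs=1e-4)

    def test_poisson_limit_matches_independent_oracle(self, rng):
        y, X = simulate_nb(rng, 2000, (0.3, 0.5), alpha=1e-12)
        fit = fit_negative_binomial(y, X)
        oracle = poisson_mle_oracle(y, X["x"].to_numpy())
        assert fit.params["const"] == pytest.approx(oracle[0], abs=1e-3)
        assert fit.params["x"] == pytest.approx(oracle[1], abs=1e-3)

    def test_llf_at_optimum_beats_truth(self, rng):
        beta, alpha = (0.2, 0.6), 0.8
        y, X = simulate_nb(rng, 500, beta, alpha)
        fit = fit_negative_binomial(y, X)
        mu_true = np.exp(beta[0] + beta[1] * X["x"].to_numpy())
        assert fit.llf >= nb2_loglike(y, mu_true, alpha) - 1e-8

    def test_aic_bic_arithmetic(self, rng):
        y, X = simulate_nb(rng, 300, (0.2, 0.4), 0.5)
        fit = fit_negative_binomial(y, X)
        k = len(fit.params) + 1  # betas plus the dispersion
        assert fit.aic == pytest.approx(-2 * fit.llf + 2 * k)
        assert fit.bic == pytest.approx(-2 * fit.llf + k * math.log(300))

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            fit_negative_binomial(np.zeros(50), pd.DataFrame({"x": np.arange(50.0)}))

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.normal(size=60)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="rank deficient"):
            fit_negative_binomial(rng.poisson(2, 60), X)

    def test_covariance_symmetric_psd(self, rng):
        y, X = simulate_nb(rng, 500, (0.2, 0.4), 0.5)
        fit = fit_negative_binomial(y, X)
        c = fit.cov.to_numpy()
        assert np.allclose(c, c.T, atol=1e-10)
        assert np.all(np.linalg.eigvalsh(c) > -1e-10)


class TestWaldTable:
    @staticmethod
    def make_fit(beta, se_vals):
        names = [f"b{i}" for i in range(len(beta))]
        cov = pd.DataFrame(np.diag(np.asarray(se_vals) ** 2), index=names, columns=names)
        # pad the dispersion row/col the way a real fit carries it
        cov.loc["alpha", :] = 0.0
        cov.loc[:, "alpha"] = 0.0
        cov.loc["alpha", "alpha"] = 1.0
        return NBFit(
            params=pd.Series(beta, index=names),
            alpha=0.5,
            cov=cov,
            llf=-10.0,
            n=50,
            linear_predictor=np.zeros(50),
            exog_names=tuple(names),
        )

    def test_null_coefficient_interval(self):
        table = wald_exp_coefficients(self.make_fit([0.0], [0.1]))
        assert table.loc["b0", "exp_b"] == pytest.approx(1.0)
        assert table.loc["b0", "ci_low"] == pytest.approx(0.82, abs=0.005)
        assert table.loc["b0", "ci_high"] == pytest.approx(1.22, abs=0.005)

    def test_backsolved_se_reproduces_published_style_interval(self):
        # a Wald CI of (1.16, 4.22) around Exp(B) ~ 2.22 implies
        # SE = (ln 4.22 - ln 1.16) / (2 * 1.96) = 0.3294; the point estimate
        # is the geometric midpoint of the interval
        se = (math.log(4.22) - math.log(1.16)) / (2 * 1.96)
        b = 0.5 * (math.log(4.22) + math.log(1.16))
        assert math.exp(b) == pytest.approx(2.22, abs=0.02)
        table = wald_exp_coefficients(self.make_fit([b], [se]))
        assert table.loc["b0", "ci_low"] == pytest.approx(1.16, abs=0.01)
        assert table.loc["b0", "ci_high"] == pytest.approx(4.22, abs=0.01)

    def test_interval_always_contains_point_estimate(self, rng):
        beta = rng.normal(0, 1, 5)
        ses = rng.uniform(0.05, 0.5, 5)
        table = wald_exp_coefficients(self.make_fit(beta, ses))
        assert np.all(table["ci_low"] <= table["exp_b"])
        assert np.all(table["exp_b"] <= table["ci_high"])


class TestScreen:
    def test_force_include_contract(self, rng):
        y = rng.poisson(2, 200)
        X = pd.DataFrame(rng.normal(size=(200, 3)), columns=["a", "b", "c"])
        res = univariate_screen(y, X, force_include=("b",))
        assert "b" in res.selected

    def test_informative_column_always_selected(self, rng):
        y = rng.poisson(2, 200)
        X = pd.DataFrame(
            {"signal": np.log(y + 1.0) + rng.normal(0, 0.05, 200),
             "noise": rng.normal(size=200)}
        )
        res = univariate_screen(y, X)
        assert "signal" in res.selected

    def test_type_one_error_near_ten_percent(self):
        hits = 0
        reps = 200
        for i in range(reps):
            rng = np.random.default_rng(10_000 + i)
            y = rng.poisson(2, 80)
            X = pd.DataFrame({"noise": rng.normal(size=80)})
            res = univariate_screen(y, X)
            hits += "noise" in res.selected
        # Binomial(200, 0.10): +-3 sigma band around the nominal level
        assert 0.04 <= hits / reps <= 0.16


class TestVIF:
    def test_orthogonal_columns_give_unity(self):
        q, _ = np.linalg.qr(np.random.default_rng(0).normal(size=(100, 3)))
        out = vif(pd.DataFrame(q, columns=list("abc")))
        # orthogonal but not mean-centred: allow tiny deviation from 1
        assert np.all(out < 1.2)

    def test_exact_collinearity_is_infinite(self, rng):
        a, b = rng.normal(size=100), rng.normal(size=100)
        out = vif(pd.DataFrame({"a": a, "b": b, "c": a + b}))
        assert np.isinf(out["c"])

    def test_matches_r2_oracle(self, rng):
        a = rng.normal(size=400)
        b = math.sqrt(0.75) * a + math.sqrt(0.25) * rng.normal(size=400)
        X = pd.DataFrame({"a": a, "b": b})
        xc = np.column_stack([np.ones(400), a])
        coef, *_ = np.linalg.lstsq(xc, b, rcond=None)
        resid = b - xc @ coef
        r2 = 1 - resid @ resid / ((b - b.mean()) @ (b - b.mean()))
        assert vif(X)["b"] == pytest.approx(1.0 / (1.0 - r2), rel=1e-9)


class TestLinearPredictor:
    def test_two_computations_agree(self, rng):
        y, X = simulate_nb(rng, 300, (0.2, 0.4), 0.5)
        fit = fit_negative_binomial(y, X)
        eta = linear_predictor(fit, X)
        manual = np.array(
            [fit.params["const"] + fit.params["x"] * v for v in X["x"]]
        )
        np.testing.assert_allclose(eta, manual, atol=1e-12)

    def test_column_mismatch_is_informative(self, rng):
        y, X = simulate_nb(rng, 300, (0.2, 0.4), 0.5)
        fit = fit_negative_binomial(y, X)
        with pytest.raises(ValueError, match="missing columns"):
            linear_predictor(fit, pd.DataFrame({"z": X["x"]}))


class TestModelSearch:
    @pytest.fixture()
    def cohort(self, rng):
        n = 150
        basic = pd.DataFrame(
            {"age": rng.normal(5.5, 1.3, n), "dm": rng.integers(0, 2, n).astype(float)}
        )
        delta = pd.DataFrame(
            {"d_hf": rng.normal(0, 2, n), "d_tp": rng.normal(0, 3, n)}
        )
        eta = -0.5 + 0.2 * basic["age"] + 0.5 * basic["dm"] - 0.35 * delta["d_hf"]
        y = rng.poisson(np.exp(eta))
        if not (y >= 1).any() or (y >= 1).all():
            y[0] = 1 - y[0]
        return y, basic, delta

    def test_empty_delta_set_gives_basic_only(self, cohort):
        y, basic, _ = cohort
        res = model_search(y, basic, pd.DataFrame(index=basic.index))
        assert res.best.added == ()
        assert res.candidates == []

    def test_duplicated_column_excluded_by_vif(self, cohort):
        y, basic, delta = cohort
        delta = delta.copy()
        delta["d_tp_copy"] = delta["d_tp"]
        res = model_search(y, basic, delta, max_added=2)
        dup = [c for c in res.candidates if set(c.added) == {"d_tp", "d_tp_copy"}]
        assert dup and dup[0].excluded is not None

    def test_informative_delta_improves_ranking(self, cohort):
        y, basic, delta = cohort
        res = model_search(y, basic, delta, max_added=2)
        assert "d_hf" in res.best.added
        assert res.best.auc >= res.basic.auc

    def test_table_lists_basic_first(self, cohort):
        y, basic, delta = cohort
        table = model_search(y, basic, delta, max_added=1).table()
        assert table.iloc[0]["model"] == "basic"
        assert {"auc", "aic", "bic", "max_vif"} <= set(table.columns)
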