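import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from immunodyn.dynamics import DynamicsMatrix
from immunodyn.errors import ValidationError
from immunodyn.predictive_model import (ModelResult, binomial_deviance,
                                        evaluate_predictions,
                                        fit_lambda_path,
                                        fit_penalized_logistic, lambda_max,
                                        lambda_path, penalized_loglik,
                                        repeated_holdout, select_lambda)
from immunodyn import univariate_stats


def random_instance(rng, n=20, p=5, signal=0.0):
    X = rng.normal(size=(n, p))
    y = np.r_[np.ones(n // 2), np.zeros(n - n // 2)]
    rng.shuffle(y)
    X[:, 0] += signal * y
    return X, y


def brute_force_objective(X, y, lam, restarts=6, seed=0):
    """Independent penalized-likelihood optimum.

    Uses the smooth split beta = beta+ - beta- (both non-negative), which
    turns the L1 objective into a box-constrained smooth problem solvable
    by L-BFGS-B, cross-checked with Nelder-Mead restarts on the raw
    non-smooth parametrization.
    """
    rng = np.random.default_rng(seed)
    p = X.shape[1]

    def neg_raw(params):
        b, beta = params[0], params[1:]
        z = X @ beta + b
        return float(np.sum(np.logaddexp(0.0, z) - y * z)
                     + lam * np.abs(beta).sum())

    def neg_split(params):
        b = params[0]
        beta = params[1:p + 1] - params[p + 1:]
        z = X @ beta + b
        pr = 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))
        val = float(np.sum(np.logaddexp(0.0, z) - y * z)
                    + lam * params[1:].sum())
        g_z = pr - y
        g_b = g_z.sum()
        g_beta = X.T @ g_z
        grad = np.r_[g_b, g_beta + lam, -g_beta + lam]
        return val, grad

    bounds = [(None, None)] + [(0.0, None)] * (2 * p)
    best = np.inf
    for r in range(restarts):
        x0 = np.zeros(2 * p + 1) if r == 0 \
            else np.r_[rng.normal(), np.abs(rng.normal(size=2 * p)) * 0.3]
        res = minimize(neg_split, x0, jac=True, method="L-BFGS-B",
                       bounds=bounds,
                       options=dict(maxiter=20_000, ftol=1e-16, gtol=1e-12))
        best = min(best, res.fun)
        res_nm = minimize(neg_raw, np.zeros(p + 1) if r == 0
                          else rng.normal(size=p + 1) * 0.5,
                          method="Nelder-Mead",
                          options=dict(maxiter=20_000, maxfev=20_000,
                                       xatol=1e-10, fatol=1e-14))
        best = min(best, res_nm.fun)
    return -best  # as a maximized log-likelihood


class TestFit:
    def test_lambda_max_null_model(self, rng):
        X, y = random_instance(rng)
        lmax = lambda_max(X, y)
        fit = fit_penalized_logistic(X, y, lmax)
        assert (fit.beta == 0).all()
        assert fit.intercept == pytest.approx(
            np.log(y.mean() / (1 - y.mean())), abs=1e-12)
        # strictly above lambda_max as well
        fit2 = fit_penalized_logistic(X, y, 2 * lmax)
        assert (fit2.beta == 0).all()

    def test_objective_matches_brute_force(self, rng):
        X, y = random_instance(rng)
        fit = fit_penalized_logistic(X, y, 0.1)
        oracle = brute_force_objective(X, y, 0.1)
        assert fit.objective == pytest.approx(oracle, abs=1e-5)

    def test_objective_value_is_penalized_loglik(self, rng):
        X, y = random_instance(rng)
        fit = fit_penalized_logistic(X, y, 0.3)
        assert fit.objective == pytest.approx(
            penalized_loglik(X, y, fit.beta, fit.intercept, 0.3), abs=1e-12)

    def test_monotone_objective_trace(self, rng):
        for seed in range(5):
            X, y = random_instance(np.random.default_rng(seed), n=30, p=8)
            fit = fit_penalized_logistic(X, y, 0.05, keep_trace=True)
            trace = fit.objective_trace  # maximized form, should increase
            assert (np.diff(trace) >= -1e-9).all()

    def test_separable_limit(self):
        # single perfectly separating feature, lam=0: ordering preserved
        x = np.array([[-2.0], [-1.5], [-1.0], [1.0], [1.5], [2.0]])
        y = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        fit = fit_penalized_logistic(x, y, 0.0, max_outer=200)
        p = fit.predict_proba(x)
        assert (p[y == 1].min() > p[y == 0].max())
        assert fit.beta[0] > 5  # diverging up to the iteration cap

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            fit_penalized_logistic(np.zeros((4, 2)), np.ones(4), 0.1)

    def test_nonfinite_rejected(self):
        X = np.zeros((4, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValidationError):
            fit_penalized_logistic(X, np.array([0, 1, 0, 1.0]), 0.1)

    def test_warm_path_matches_cold_fits(self, rng):
        X, y = random_instance(rng, n=25, p=10)
        Xs = (X - X.mean(0)) / X.std(0)
        lambdas = lambda_path(Xs, y, n_lambdas=20)
        betas, intercepts = fit_lambda_path(Xs, y, lambdas, tol=1e-12,
                                            inner_tol=1e-10)
        for k in [0, 5, 10, 19]:
            warm_obj = penalized_loglik(Xs, y, betas[k], intercepts[k],
                                        lambdas[k])
            cold = fit_penalized_logistic(Xs, y, lambdas[k], tol=1e-12,
                                          inner_tol=1e-10)
            assert warm_obj == pytest.approx(cold.objective, abs=1e-6)


class TestSelectLambda:
    def test_null_deviance_at_lambda_max(self, rng):
        X, y = random_instance(rng)
        fit = fit_penalized_logistic(X, y, lambda_max(X, y))
        dev = binomial_deviance(y, fit.predict_proba(X))
        p0 = y.mean()
        null_dev = -2 * np.mean(y * np.log(p0) + (1 - y) * np.log(1 - p0))
        assert dev == pytest.approx(null_dev, abs=1e-10)

    def test_pure_noise_selects_sparse(self):
        sparse = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X, y = random_instance(rng, n=20, p=20)
            Xs = (X - X.mean(0)) / X.std(0)
            lam = select_lambda(Xs, y, seed=seed)
            support = int((fit_penalized_logistic(Xs, y, lam).beta != 0).sum())
            sparse += support <= 1
        assert sparse >= 40  # >= 80% of seeds

    def test_huge_effect_feature_selected(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            X, y = random_instance(rng, n=20, p=10, signal=5.0)
            Xs = (X - X.mean(0)) / X.std(0)
            lam = select_lambda(Xs, y, seed=seed)
            hits += fit_penalized_logistic(Xs, y, lam).beta[0] != 0
        assert hits >= 48  # >= 95% of seeds

    def test_deterministic_given_seed(self, rng):
        X, y = random_instance(rng, n=22, p=15)
        assert select_lambda(X, y, seed=3) == select_lambda(X, y, seed=3)


class TestEvaluatePredictions:
    def test_perfect_ranking(self):
        auc, p = evaluate_predictions([0.9, 0.8, 0.7, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_three_of_four_pairs(self):
        auc, _ = evaluate_predictions([0.9, 0.4, 0.7, 0.1], [1, 1, 0, 0])
        assert auc == 0.75

    def test_sign_reversal_symmetry(self, rng):
        preds = rng.random(12)
        labels = np.r_[np.ones(6), np.zeros(6)]
        auc1, _ = evaluate_predictions(preds, labels)
        auc2, _ = evaluate_predictions(-preds, labels)
        assert auc1 + auc2 == pytest.approx(1.0)

    def test_constant_predictions(self):
        with pytest.warns(UserWarning):
            auc, p = evaluate_predictions([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert (auc, p) == (0.5, 1.0)

    def test_shared_auc_implementation(self):
        # one implementation serves both this module and univariate_stats
        from immunodyn.predictive_model import roc_auc as model_auc
        assert model_auc is univariate_stats.roc_auc


def _null_dynamics(seed, n=11, p=12):
    rng = np.random.default_rng(seed)
    patients = [f"P{i:02d}" for i in range(n)]
    values = pd.DataFrame(rng.normal(size=(n, p)),
                          index=pd.Index(patients, name="patient"),
                          columns=[f"f{j}" for j in range(p)])
    sheet = pd.DataFrame({"patient": patients,
                          "group": ["control"] * (n // 2)
                          + ["case"] * (n - n // 2)})
    return DynamicsMatrix(values, pd.DataFrame(index=values.columns), sheet)


class TestRepeatedHoldout:
    def test_coverage_topup(self):
        D = _null_dynamics(0)
        res = repeated_holdout(D, n_iterations=1, seed=4, n_lambdas=20)
        assert res.n_iterations_total > 1
        assert all(len(v) >= 1 for v in res.predictions_per_patient.values())
        assert res.final_predictions.between(0, 1).all()

    def test_deterministic(self):
        D = _null_dynamics(1)
        r1 = repeated_holdout(D, n_iterations=8, seed=9, n_lambdas=20)
        r2 = repeated_holdout(D, n_iterations=8, seed=9, n_lambdas=20)
        pd.testing.assert_series_equal(r1.final_predictions,
                                       r2.final_predictions)
        assert r1.auc == r2.auc and r1.p_value == r2.p_value

    def test_too_small_cohort_rejected(self):
        D = _null_dynamics(2, n=6)
        with pytest.raises(ValidationError):
            repeated_holdout(D, n_test=3)

    def test_zero_noise_planted_recovery(self):
        # a single noiseless discriminative feature is always in the support
        for seed in range(5):
            rng = np.random.default_rng(seed)
            D = _null_dynamics(seed, n=12, p=6)
            labels = (D.sheet["group"] == "case").astype(float).to_numpy()
            D.values["f0"] = labels * 0.2 - 0.1
            Xs = (D.values.to_numpy() - D.values.to_numpy().mean(0)) \
                / D.values.to_numpy().std(0)
            lam = select_lambda(Xs, labels, seed=seed)
            fit = fit_penalized_logistic(Xs, labels, lam)
            assert fit.beta[0] != 0

    def test_json_roundtrip(self, tmp_path):
        D = _null_dynamics(3)
        res = repeated_holdout(D, n_iterations=5, seed=2, n_lambdas=20)
        res.to_json(tmp_path / "model.json")
        back = ModelResult.from_json(tmp_path / "model.json")
        assert back.auc == res.auc
        assert back.feature_names == res.feature_names
        assert np.allclose(back.coef_matrix, res.coef_matrix, atol=1e-10)
        pd.testing.assert_series_equal(
            back.final_predictions.astype(float).rename(None),
            res.final_predictions.round(10).rename(None))
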