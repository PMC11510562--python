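import numpy as np
import pytest

import solmap as sm
from solmap.bayes_ridge import (
    BayesianRidge,
    BayesianRidgeResults,
    DegenerateDataError,
    evaluate_predictions,
    ridge_solve,
)
from solmap.fingerprint import compute_circular_fingerprint, parse_smiles


def normal_equations_ridge(X, y, alpha, beta):
    """Independent oracle: centered penalized normal equations, solved densely."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    p = X.shape[1]
    m = np.linalg.solve(alpha * np.eye(p) + beta * Xc.T @ Xc, beta * Xc.T @ yc)
    return m, y.mean() - m @ X.mean(axis=0)


def random_problem(rng, n=None, p=None):
    n = n or int(rng.integers(5, 101))
    p = p or int(rng.integers(1, 51))
    X = rng.normal(size=(n, p))
    y = X @ rng.normal(size=p) + rng.normal(size=n)
    return X, y


class TestRidgeSolve:
    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(20):
            X, y = random_problem(rng)
            alpha = float(10 ** rng.uniform(-3, 2))
            beta = float(10 ** rng.uniform(-1, 2))
            m, b = ridge_solve(X, y, alpha, beta)
            m_ref, b_ref = normal_equations_ridge(X, y, alpha, beta)
            assert np.max(np.abs(m - m_ref)) < 1e-10
            assert abs(b - b_ref) < 1e-10

    def test_vanishing_penalty_recovers_ols(self, rng):
        X, y = random_problem(rng, n=60, p=5)
        m, _ = ridge_solve(X, y, 1e-12, 1.0)
        Xc = X - X.mean(axis=0)
        ols = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
        assert np.max(np.abs(m - ols)) < 1e-8

    def test_zero_targets_give_zero_solution(self, rng):
        X = rng.normal(size=(30, 4))
        m, b = ridge_solve(X, np.zeros(30), 1.0, 1.0)
        assert np.allclose(m, 0) and b == 0.0

    def test_classical_ridge_equivalence(self, rng):
        # for fixed hyperparameters the fit depends only on lambda = alpha/beta
        X, y = random_problem(rng, n=40, p=8)
        m1, b1 = ridge_solve(X, y, 3.0, 2.0)
        m2, b2 = ridge_solve(X, y, 1.5, 1.0)
        assert np.max(np.abs(m1 - m2)) < 1e-10 and abs(b1 - b2) < 1e-10

    def test_rejects_bad_input(self, rng):
        X, y = random_problem(rng, n=30, p=3)
        with pytest.raises(ValueError):
            ridge_solve(X, y, -1.0, 1.0)
        with pytest.raises(DegenerateDataError):
            ridge_solve(X[:1], y[:1], 1.0, 1.0)


class TestEvidenceMaximization:
    def test_noiseless_data_reproduced(self, rng):
        X = rng.normal(size=(200, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + 3.0
        res = BayesianRidge(X, y).fit()
        assert res.converged
        assert res.evaluate().rmse < 1e-3

    def test_noise_precision_recovery(self, rng):
        X = rng.normal(size=(1000, 10))
        y = X @ rng.normal(size=10) + rng.normal(scale=0.5, size=1000)
        res = BayesianRidge(X, y).fit()
        assert 0.4 < res.noise_sd < 0.6

    def test_scale_equivariance(self, rng):
        X, y = random_problem(rng, n=150, p=6)
        r1 = BayesianRidge(X, y).fit(tol=1e-12, max_iter=2000)
        r2 = BayesianRidge(X, 2 * y).fit(tol=1e-12, max_iter=2000)
        assert np.allclose(r2.weights, 2 * r1.weights, rtol=1e-6)
        assert np.isclose(r2.intercept, 2 * r1.intercept, rtol=1e-6)
        assert np.isclose(r2.beta, r1.beta / 4, rtol=1e-5)

    def test_log_evidence_non_decreasing(self, rng):
        for _ in range(5):
            X, y = random_problem(rng, n=80, p=12)
            res = BayesianRidge(X, y).fit()
            assert np.all(np.diff(res.log_evidence) >= -1e-8)

    def test_agrees_with_sklearn_reference(self, rng):
        sklearn = pytest.importorskip("sklearn.linear_model")
        X = rng.normal(size=(200, 8))
        y = X @ rng.normal(size=8) + 0.5 + rng.normal(scale=0.4, size=200)
        res = BayesianRidge(X, y).fit(tol=1e-10, max_iter=2000)
        sk = sklearn.BayesianRidge(
            alpha_1=0, alpha_2=0, lambda_1=0, lambda_2=0, tol=1e-10, max_iter=2000
        ).fit(X, y)
        # sklearn calls the weight precision lambda_ and the noise precision alpha_
        assert np.max(np.abs(res.weights - sk.coef_)) < 1e-8
        assert abs(res.intercept - sk.intercept_) < 1e-8
        assert np.isclose(res.alpha, sk.lambda_, rtol=1e-6)
        assert np.isclose(res.beta, sk.alpha_, rtol=1e-6)

    def test_rejects_constant_targets(self, rng):
        X = rng.normal(size=(20, 3))
        with pytest.raises(DegenerateDataError):
            BayesianRidge(X, np.full(20, 2.5))

    def test_unconverged_fit_is_flagged(self, rng):
        X, y = random_problem(rng, n=100, p=10)
        res = BayesianRidge(X, y).fit(max_iter=1, tol=1e-14)
        assert not res.converged and res.n_iter == 1


class TestPrediction:
    def test_empty_fingerprint_predicts_intercept(self, fitted_results):
        fp = sm.FingerprintResult(nbits=2048, radius=2)
        assert fitted_results.predict(fp) == fitted_results.intercept

    def test_fingerprint_prediction_equals_dense_dot_product(self, fitted_results):
        fp = compute_circular_fingerprint(parse_smiles(sm.MP_SMILES))
        dense = float(fp.dense() @ fitted_results.weights + fitted_results.intercept)
        assert np.isclose(fitted_results.predict(fp), dense, atol=1e-12)

    def test_nbits_mismatch_rejected(self, fitted_results):
        fp = compute_circular_fingerprint(parse_smiles("CC"), nbits=512)
        with pytest.raises(ValueError):
            fitted_results.predict(fp)

    def test_json_roundtrip_preserves_predictions(self, fitted_results, tmp_path):
        path = tmp_path / "model.json"
        fitted_results.to_json(path)
        loaded = BayesianRidgeResults.from_json(path)
        for smi in ("CCO", "CC(=O)O", sm.MP_SMILES):
            assert np.isclose(
                loaded.predict_smiles(smi), fitted_results.predict_smiles(smi)
            )


class TestEvaluate:
    def test_perfect_predictions(self):
        m = evaluate_predictions([0.0, 1.0, 2.0], [0.0, 1.0, 2.0])
        assert m.rmse == 0.0 and m.r_squared == 1.0

    def test_mean_prediction_gives_zero_r_squared(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = evaluate_predictions(y, np.full(4, y.mean()))
        assert np.isclose(m.r_squared, 0.0)

    def test_hand_computed_three_point_case(self):
        m = evaluate_predictions([0.0, 1.0, 2.0], [0.0, 1.0, 1.0])
        assert np.isclose(m.rmse, np.sqrt(1 / 3))
        assert np.isclose(m.r_squared, 0.5)

    def test_constant_targets_rejected(self):
        with pytest.raises(DegenerateDataError):
            evaluate_predictions([1.0, 1.0], [1.0, 2.0])
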