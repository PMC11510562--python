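"""Bayesian ridge regression on fingerprint bits, from closed form.

Model
-----
Linear-Gaussian model for logS (log10 aqueous solubility, mol/L):

    y_i = b + phi_i . m + eps_i,   eps_i ~ N(0, 1/beta)
    m_j ~ N(0, 1/alpha)

with a binary fingerprint row ``phi_i``.  For fixed hyperparameters the
posterior mean of the weights is the ridge solution

    m = beta (alpha I + beta Phi_c' Phi_c)^{-1} Phi_c' y_c

where ``Phi_c`` and ``y_c`` are column- and target-centered so the intercept
``b = mean(y) - m . column_means`` is unpenalized.  Hyperparameters are set
by type-II maximum likelihood (evidence maximization, MacKay updates):

    gamma  = sum_j lambda_j / (alpha + lambda_j),  lambda_j = eigenvalues of beta Phi_c' Phi_c
    alpha <- gamma / (m . m)
    beta  <- (N - gamma) / ||y_c - Phi_c m||^2

iterated until both hyperparameters change by less than ``tol`` (relative).
All linear algebra goes through one thin SVD of ``Phi_c``, so each update is
O(min(n, p)) after the initial decomposition.

The public surface is a statsmodels-style pair: :class:`BayesianRidge` is
built from data and ``fit()`` returns :class:`BayesianRidgeResults` carrying
the estimates, hyperparameters, fit diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fingerprint as fpmod
from .fingerprint import FingerprintResult

__all__ = [
    "BayesianRidge",
    "BayesianRidgeResults",
    "FitMetrics",
    "ridge_solve",
    "evaluate_predictions",
]


class DegenerateDataError(ValueError):
    """Raised for inputs a linear-Gaussian fit cannot use (n < 2, constant y)."""


def _validate(Phi: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Phi = np.asarray(Phi, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if Phi.ndim != 2:
        raise ValueError("Phi must be 2-D")
    if Phi.shape[0] != y.shape[0]:
        raise ValueError(f"rows(Phi)={Phi.shape[0]} != len(y)={y.shape[0]}")
    if y.shape[0] < 2:
        raise DegenerateDataError("need at least 2 observations")
    return Phi, y


def ridge_solve(
    Phi: np.ndarray, y: np.ndarray, alpha: float, beta: float
) -> tuple[np.ndarray, float]:
    """Posterior-mean weights and intercept for fixed (alpha, beta).

    Exact minimizer of ``beta ||y_c - Phi_c m||^2 + alpha ||m||^2`` with the
    intercept recovered from the centering identity.  Deterministic.
    """
    Phi, y = _validate(Phi, y)
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be > 0")
    col_means = Phi.mean(axis=0)
    y_mean = y.mean()
    Phic = Phi - col_means
    yc = y - y_mean
    U, s, Vt = np.linalg.svd(Phic, full_matrices=False)
    # m = beta V diag(s / (alpha + beta s^2)) U' y_c
    coef = (beta * s / (alpha + beta * s**2)) * (U.T @ yc)
    m = Vt.T @ coef
    b = y_mean - m @ col_means
    return m, float(b)


@dataclass
class FitMetrics:
    """Goodness-of-fit numbers: RMSE (logS units) and coefficient of determination."""

    rmse: float
    r_squared: float


def evaluate_predictions(y: np.ndarray, y_hat: np.ndarray) -> FitMetrics:
    """RMSE and R^2 of predictions against observed targets."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape:
        raise ValueError("shape mismatch between y and predictions")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateDataError("R^2 undefined for constant y")
    ss_res = float(np.sum((y - y_hat) ** 2))
    return FitMetrics(
        rmse=float(np.sqrt(np.mean((y - y_hat) ** 2))),
        r_squared=1.0 - ss_res / ss_tot,
    )


class BayesianRidge:
    """Bayesian ridge regression model over fingerprint bits.

    Parameters
    ----------
    Phi : (n, p) array
        Binary design matrix of fingerprint bits.
    y : (n,) array
        logS targets.
    radius, nbits : int, optional
        Fingerprint configuration recorded for provenance and for
        fingerprinting query molecules at predict time.

    Use :meth:`from_dataframe` to build directly from a molecule table with
    ``smiles`` and ``logS`` columns.
    """

    def __init__(self, Phi, y, radius: int = fpmod.DEFAULT_RADIUS, nbits: int | None = None):
        self.Phi, self.y = _validate(Phi, y)
        if np.ptp(self.y) == 0.0:
            raise DegenerateDataError("y is constant; noise precision unidentifiable")
        self.radius = radius
        self.nbits = int(self.Phi.shape[1] if nbits is None else nbits)
        if self.nbits != self.Phi.shape[1]:
            raise ValueError("nbits must equal the number of design-matrix columns")

    @classmethod
    def from_dataframe(
        cls,
        table: pd.DataFrame,
        radius: int = fpmod.DEFAULT_RADIUS,
        nbits: int = fpmod.DEFAULT_NBITS,
        smiles_col: str = "smiles",
        target_col: str = "logS",
    ) -> "BayesianRidge":
        """Featurize a ``smiles``/``logS`` table and build the model."""
        Phi = fpmod.featurize_table(table, radius=radius, nbits=nbits, smiles_col=smiles_col)
        return cls(Phi, table[target_col].to_numpy(), radius=radius, nbits=nbits)

    def fit(
        self,
        max_iter: int = 300,
        tol: float = 1e-4,
        alpha0: float = 1.0,
        beta0: float | None = None,
    ) -> "BayesianRidgeResults":
        """Fit by evidence maximization; returns a results object.

        ``beta0`` defaults to the reciprocal target variance.  A model that
        exhausts ``max_iter`` is returned with ``converged=False``.
        """
        Phi, y = self.Phi, self.y
        n = y.shape[0]
        col_means = Phi.mean(axis=0)
        y_mean = y.mean()
        Phic = Phi - col_means
        yc = y - y_mean
        U, s, Vt = np.linalg.svd(Phic, full_matrices=False)
        Uty = U.T @ yc
        s2 = s**2
        yc_sq = float(yc @ yc)

        alpha = float(alpha0)
        beta = float(1.0 / np.var(y)) if beta0 is None else float(beta0)
        log_evidence: list[float] = []
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            coef = (beta * s / (alpha + beta * s2)) * Uty
            m = Vt.T @ coef
            mtm = float(m @ m)
            # residual via SVD identity: Phic m has coordinates s*coef in U-basis
            rss = yc_sq - 2.0 * float((s * coef) @ Uty) + float((s * coef) @ (s * coef))
            rss = max(rss, np.finfo(float).tiny)
            log_evidence.append(self._log_marginal(alpha, beta, s2, n, mtm, rss))
            lam = beta * s2
            gamma = float(np.sum(lam / (alpha + lam)))
            alpha_new = gamma / mtm if mtm > 0 else alpha
            beta_new = (n - gamma) / rss
            if (
                abs(alpha_new - alpha) < tol * abs(alpha)
                and abs(beta_new - beta) < tol * abs(beta)
            ):
                alpha, beta = alpha_new, beta_new
                converged = True
                break
            alpha, beta = alpha_new, beta_new

        coef = (beta * s / (alpha + beta * s2)) * Uty
        m = Vt.T @ coef
        b = y_mean - m @ col_means
        return BayesianRidgeResults(
            model=self,
            weights=m,
            intercept=float(b),
            alpha=alpha,
            beta=beta,
            n_iter=n_iter,
            converged=converged,
            log_evidence=np.asarray(log_evidence),
        )

    @staticmethod
    def _log_marginal(alpha, beta, s2, n, mtm, rss) -> float:
        """Log marginal likelihood (evidence) at the current posterior mode."""
        p_eff = s2.shape[0]
        logdet_A = float(np.sum(np.log(alpha + beta * s2)))
        return 0.5 * (
            p_eff * np.log(alpha)
            + n * np.log(beta)
            - beta * rss
            - alpha * mtm
            - logdet_A
            - n * np.log(2.0 * np.pi)
        )


class BayesianRidgeResults:
    """Estimates and diagnostics from a :class:`BayesianRidge` fit.

    Attributes
    ----------
    weights : (p,) array
        Posterior-mean bit coefficients (logS units per bit).
    intercept : float
        Unpenalized intercept (logS units).
    alpha, beta : float
        Converged prior and noise precisions; ``1/sqrt(beta)`` estimates the
        residual noise standard deviation.
    n_iter : int
        Evidence-update iterations used.
    converged : bool
    log_evidence : array
        Log marginal likelihood trace across iterations.
    """

    def __init__(self, model, weights, intercept, alpha, beta, n_iter, converged, log_evidence):
        self.model = model
        self.weights = np.asarray(weights, dtype=float)
        self.intercept = float(intercept)
        self.alpha = float(alpha)
        self.beta = float(beta)
        self.n_iter = int(n_iter)
        self.converged = bool(converged)
        self.log_evidence = np.asarray(log_evidence, dtype=float)

    # -- prediction ---------------------------------------------------------

    @property
    def noise_sd(self) -> float:
        """Estimated residual standard deviation, 1/sqrt(beta)."""
        return float(1.0 / np.sqrt(self.beta))

    def predict(self, X) -> np.ndarray | float:
        """Predict logS for a design matrix or a single fingerprint.

        Accepts a dense (n, p) matrix or a :class:`FingerprintResult`, in
        which case ``b + sum of the weights of its on bits`` is returned.
        """
        if isinstance(X, FingerprintResult):
            if X.nbits != self.weights.shape[0]:
                raise ValueError(
                    f"fingerprint has {X.nbits} bits, model expects {self.weights.shape[0]}"
                )
            return self.intercept + float(sum(self.weights[j] for j in X.on_bits))
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.weights.shape[0]:
            raise ValueError("design-matrix width does not match model")
        return X @ self.weights + self.intercept

    def predict_smiles(self, smiles: str) -> float:
        """Fingerprint a SMILES with the training configuration and predict."""
        mol = fpmod.parse_smiles(smiles)
        fp = fpmod.compute_circular_fingerprint(
            mol, radius=self.model.radius, nbits=self.model.nbits
        )
        return self.predict(fp)

    def evaluate(self, Phi=None, y=None) -> FitMetrics:
        """RMSE and R^2 on the given data (training data by default)."""
        Phi = self.model.Phi if Phi is None else Phi
        y = self.model.y if y is None else y
        return evaluate_predictions(y, self.predict(Phi))

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        m = self.evaluate()
        w = self.weights[self.weights != 0]
        lines = [
            "Bayesian ridge regression (evidence maximization)",
            "=" * 52,
            f"observations        {self.model.y.shape[0]:>12d}",
            f"fingerprint bits    {self.weights.shape[0]:>12d}",
            f"active bits         {w.shape[0]:>12d}",
            f"alpha (prior prec.) {self.alpha:>12.5g}",
            f"beta (noise prec.)  {self.beta:>12.5g}",
            f"noise sd (1/sqrt b) {self.noise_sd:>12.4f}",
            f"intercept           {self.intercept:>12.4f}",
            f"iterations          {self.n_iter:>12d}  converged={self.converged}",
            f"train RMSE          {m.rmse:>12.4f}",
            f"train R^2           {m.r_squared:>12.4f}",
        ]
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------

    def to_json(self, path=None, provenance: dict | None = None) -> str:
        """Serialize the fitted model to JSON (optionally writing to ``path``)."""
        payload = {
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "alpha": self.alpha,
            "beta": self.beta,
            "nbits": self.model.nbits,
            "radius": self.model.radius,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "provenance": provenance or {},
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "BayesianRidgeResults":
        """Load a serialized model; ``source`` is a path or a JSON string."""
        try:
            with open(source) as fh:
                payload = json.load(fh)
        except (OSError, TypeError):
            payload = json.loads(source)
        weights = np.asarray(payload["weights"], dtype=float)
        shell = _ModelShell(payload["nbits"], payload["radius"])
        return cls(
            model=shell,
            weights=weights,
            intercept=payload["intercept"],
            alpha=payload["alpha"],
            beta=payload["beta"],
            n_iter=payload["n_iter"],
            converged=payload["converged"],
            log_evidence=np.empty(0),
        )


class _ModelShell:
    """Minimal stand-in for a BayesianRidge when loading from JSON: carries
    only the fingerprint configuration needed for prediction."""

    def __init__(self, nbits: int, radius: int):
        self.nbits = int(nbits)
        self.radius = int(radius)
        self.Phi = None
        self.y = None
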