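"""Genomic BLUP with reliability-weighted residuals.

The mixed model is y = 1 mu + Z g + e with g ~ N(0, G sigma_g^2) and
e ~ N(0, D sigma_e^2), where G is the VanRaden (method 1) genomic
relationship matrix and D is diagonal with d_ii = (1 - r_i^2)/r_i^2 from
each animal's DRP reliability. Variance components maximize the REML
log-likelihood; after whitening by D^{-1/2} the covariance is
sigma_g^2 A + sigma_e^2 I with A = D^{-1/2} G D^{-1/2}, so one
eigendecomposition reduces REML to a one-dimensional search over the
variance ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted


def build_grm(dosages: np.ndarray, p: np.ndarray | None = None) -> np.ndarray:
    """VanRaden method-1 GRM: G = WW' / (2 sum p(1-p)), W = dosages - 2p."""
    X = np.asarray(dosages, dtype=float)
    if p is None:
        p = X.mean(axis=0) / 2.0
    p = np.asarray(p, dtype=float)
    het = p * (1.0 - p)
    if np.any(het <= 0):
        j = int(np.flatnonzero(het <= 0)[0])
        raise ValueError(
            f"monomorphic SNP at column {j} (allele frequency {p[j]}); "
            "run QC before building the relationship matrix"
        )
    W = X - 2.0 * p
    return (W @ W.T) / (2.0 * float(het.sum()))


def reliability_weights(r2: np.ndarray) -> np.ndarray:
    """Diagonal residual weights d_ii = (1 - r^2)/r^2 from DRP reliabilities."""
    r2 = np.asarray(r2, dtype=float)
    if np.any((r2 <= 0) | (r2 >= 1)):
        raise ValueError("DRP reliabilities must lie strictly in (0, 1)")
    return (1.0 - r2) / r2


@dataclass
class GBLUPModel:
    G_mat: np.ndarray
    D_diag: np.ndarray
    mu: float
    sigma_g_sq: float
    sigma_e_sq: float
    gebv: np.ndarray
    reml_loglik: float | None = None

    @property
    def h2(self) -> float:
        return self.sigma_g_sq / (self.sigma_g_sq + self.sigma_e_sq)


def _reml_profile(log_gamma, dvals, w, x):
    """Negative profiled REML log-likelihood at variance ratio gamma."""
    gamma = np.exp(log_gamma)
    vi = 1.0 / (gamma * dvals + 1.0)
    xvx = float(np.sum(x * x * vi))
    xvy = float(np.sum(x * w * vi))
    mu = xvy / xvx
    resid = w - x * mu
    rss = float(np.sum(resid * resid * vi))
    n = dvals.shape[0]
    sigma_e2 = rss / (n - 1)
    ll = -0.5 * (
        (n - 1) * np.log(sigma_e2)
        + float(np.sum(np.log(gamma * dvals + 1.0)))
        + np.log(xvx)
        + (n - 1)
    )
    return -ll


def fit_gblup(
    y: np.ndarray,
    G: np.ndarray,
    D: np.ndarray | None = None,
    reml: bool = True,
    sigma_g_sq: float | None = None,
    sigma_e_sq: float | None = None,
    ridge: float = 1e-6,
) -> GBLUPModel:
    """Estimate variance components (REML) and genomic breeding values.

    With ``reml=False`` the supplied variances are used as-is. ``D`` is
    the diagonal of the residual weight matrix (defaults to identity).
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    G = np.asarray(G, dtype=float)
    Ddiag = np.ones(n) if D is None else np.asarray(D, dtype=float)
    if np.any(Ddiag <= 0):
        raise ValueError("residual weights must be positive")
    dihalf = 1.0 / np.sqrt(Ddiag)
    A = G * dihalf[:, None] * dihalf[None, :]
    A[np.diag_indices_from(A)] += ridge
    dvals, U = np.linalg.eigh(A)
    dvals = np.clip(dvals, 0.0, None)
    w = U.T @ (dihalf * y)
    x = U.T @ dihalf

    loglik = None
    if reml:
        res = minimize_scalar(
            _reml_profile, bounds=(-12.0, 12.0), method="bounded",
            args=(dvals, w, x), options={"xatol": 1e-8},
        )
        if not res.success:
            raise RuntimeError(f"REML search did not converge: {res.message}")
        gamma = float(np.exp(res.x))
        vi = 1.0 / (gamma * dvals + 1.0)
        xvx = float(np.sum(x * x * vi))
        mu = float(np.sum(x * w * vi)) / xvx
        resid = w - x * mu
        sigma_e_sq = float(np.sum(resid * resid * vi)) / (n - 1)
        sigma_g_sq = gamma * sigma_e_sq
        loglik = -float(res.fun)
    else:
        if sigma_g_sq is None or sigma_e_sq is None:
            raise ValueError("reml=False requires sigma_g_sq and sigma_e_sq")
        gamma = sigma_g_sq / sigma_e_sq
        vi = 1.0 / (gamma * dvals + 1.0)
        xvx = float(np.sum(x * x * vi))
        mu = float(np.sum(x * w * vi)) / xvx
        resid = w - x * mu

    # BLUP of g: sigma_g^2 G D^{-1/2} V~^{-1} D^{-1/2}(y - 1 mu)
    scaled = resid / (sigma_g_sq * dvals + sigma_e_sq)
    gebv = sigma_g_sq * (G @ (dihalf * (U @ scaled)))
    return GBLUPModel(
        G_mat=G, D_diag=Ddiag, mu=mu,
        sigma_g_sq=float(sigma_g_sq), sigma_e_sq=float(sigma_e_sq),
        gebv=gebv, reml_loglik=loglik,
    )


def predict_gblup(
    model: GBLUPModel,
    G_joint: np.ndarray,
    y_train: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    D_train: np.ndarray | None = None,
    ridge: float = 1e-6,
) -> np.ndarray:
    """Predict validation animals from a jointly built relationship matrix.

    g_test = G[test, train] (G[train, train] + lambda D)^-1 (y - 1 mu)
    with lambda = sigma_e^2 / sigma_g^2; the overall mean is added back so
    the output is on the trait scale.
    """
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    y_train = np.asarray(y_train, dtype=float)
    lam = model.sigma_e_sq / model.sigma_g_sq
    Dtr = np.ones(train_idx.size) if D_train is None else np.asarray(D_train, dtype=float)
    Ktt = G_joint[np.ix_(train_idx, train_idx)] + np.diag(lam * Dtr)
    rhs = y_train - model.mu
    try:
        sol = np.linalg.solve(Ktt, rhs)
    except np.linalg.LinAlgError:
        Ktt[np.diag_indices_from(Ktt)] += ridge
        sol = np.linalg.solve(Ktt, rhs)
    return model.mu + G_joint[np.ix_(test_idx, train_idx)] @ sol


class GBLUPRegressor(RegressorMixin, BaseEstimator):
    """Scikit-learn interface to reliability-weighted GBLUP.

    ``fit`` accepts raw allele dosages; the GRM is built from training
    allele frequencies and predictions for new animals use the
    cross-relationship block computed with the same frequencies. Pass
    per-animal DRP reliabilities through ``fit(..., reliabilities=...)``
    to weight residual variances.
    """

    def __init__(self, reml: bool = True, sigma_g_sq: float | None = None,
                 sigma_e_sq: float | None = None, ridge: float = 1e-6):
        self.reml = reml
        self.sigma_g_sq = sigma_g_sq
        self.sigma_e_sq = sigma_e_sq
        self.ridge = ridge

    def fit(self, X, y, reliabilities=None):
        X = check_array(X, dtype=float)
        y = check_array(y, ensure_2d=False, dtype=float)
        self._p = X.mean(axis=0) / 2.0
        het = self._p * (1.0 - self._p)
        if np.any(het <= 0):
            raise ValueError("monomorphic SNP in training data; run QC first")
        self._denom = 2.0 * float(het.sum())
        self._W_train = X - 2.0 * self._p
        G = (self._W_train @ self._W_train.T) / self._denom
        D = None if reliabilities is None else reliability_weights(reliabilities)
        self.model_ = fit_gblup(
            y, G, D, reml=self.reml,
            sigma_g_sq=self.sigma_g_sq, sigma_e_sq=self.sigma_e_sq, ridge=self.ridge,
        )
        self._y_train = y
        self._D_train = np.ones(X.shape[0]) if D is None else D
        self.sigma_g_sq_ = self.model_.sigma_g_sq
        self.sigma_e_sq_ = self.model_.sigma_e_sq
        self.h2_ = self.model_.h2
        self.mu_ = self.model_.mu
        self.gebv_ = self.model_.gebv
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = check_array(X, dtype=float)
        W_new = X - 2.0 * self._p
        G_cross = (W_new @ self._W_train.T) / self._denom
        lam = self.sigma_e_sq_ / self.sigma_g_sq_
        Ktt = self.model_.G_mat + np.diag(lam * self._D_train)
        sol = np.linalg.solve(Ktt, self._y_train - self.mu_)
        return self.mu_ + G_cross @ sol
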