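"""Whole-genome Bayesian regression by single-site Gibbs sampling.

Two mixture priors on marker effects are provided. In the first
(``fit_bayesb``) each marker has probability pi of no effect and
otherwise a scaled-t effect, realized through a per-marker slab variance
with a scaled inverse chi-square prior; pi is fixed (0.95 by default). In
the second (``fit_bayescpi``) the slab is normal with one common
variance, and pi itself is estimated with a uniform (0, 1) prior via a
Beta draw each sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from ._kernels import gibbs_core


@dataclass
class BayesConfig:
    """Chain and prior settings for the Gibbs samplers.

    Defaults follow common practice for 50k panels: 50,000 iterations,
    20,000 burn-in, every 50th retained. ``scale_S2=None`` solves the
    prior scale so the implied genetic variance matches ``h2_prior`` of
    the trait variance spread over the expected number of non-zero
    markers. ``fix_sigma_e`` / ``fix_sigma_beta`` pin those variances
    (used by the conjugate-subcase validity checks).
    """

    n_iter: int = 50_000
    burn_in: int = 20_000
    thin: int = 50
    pi: float = 0.95
    df_v: float = 4.2
    scale_S2: float | None = None
    h2_prior: float = 0.3
    seed: int = 0
    fix_sigma_e: float | None = None
    fix_sigma_beta: float | None = None

    def __post_init__(self):
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must lie in [0, 1]")


@dataclass
class BayesPosterior:
    beta_mean: np.ndarray     # posterior mean marker effects
    beta_se: np.ndarray       # posterior standard errors of marker effects
    incl_freq: np.ndarray     # posterior inclusion frequency per marker
    mu_mean: float
    sigma_e_mean: float
    sigma_b_mean: float
    pi_samples: np.ndarray | None = None
    n_samples: int = 0

    @property
    def pi_mean(self) -> float | None:
        return None if self.pi_samples is None else float(self.pi_samples.mean())


def _auto_scale(y: np.ndarray, J: int, pi: float, nu: float, h2_prior: float) -> float:
    """Prior scale so E[sigma_beta^2] matches the assumed genetic variance
    per expected non-zero marker on column-standardized genotypes."""
    vy = float(np.var(y, ddof=1))
    n_eff = max((1.0 - pi) * J, 1.0)
    mean_var = h2_prior * vy / n_eff
    return mean_var * max(nu - 2.0, 0.5) / nu


def _run_gibbs(X_std, y, cfg: BayesConfig, per_snp_var: bool, estimate_pi: bool) -> BayesPosterior:
    X_std = np.asarray(X_std, dtype=float)
    y = np.asarray(y, dtype=float)
    Xt = np.ascontiguousarray(X_std.T)
    d = np.einsum("ij,ij->j", X_std, X_std)
    J = X_std.shape[1]
    S2 = cfg.scale_S2 if cfg.scale_S2 is not None else _auto_scale(
        y, J, cfg.pi, cfg.df_v, cfg.h2_prior
    )
    out = gibbs_core(
        Xt, d, y,
        cfg.n_iter, cfg.burn_in, cfg.thin,
        per_snp_var,
        cfg.pi, estimate_pi,
        cfg.df_v, S2,
        cfg.fix_sigma_e is not None, cfg.fix_sigma_e or 1.0,
        cfg.fix_sigma_beta is not None, cfg.fix_sigma_beta or 1.0,
        int(cfg.seed) % (2**31),
    )
    beta_sum, beta_sq, incl_sum, mu_tr, pi_tr, se_tr, sb_tr, kept = out
    if not np.isfinite(beta_sum).all():
        raise FloatingPointError("non-finite marker-effect sample in Gibbs chain")
    mean = beta_sum / kept
    var = np.clip(beta_sq / kept - mean**2, 0.0, None)
    return BayesPosterior(
        beta_mean=mean,
        beta_se=np.sqrt(var),
        incl_freq=incl_sum / kept,
        mu_mean=float(mu_tr.mean()),
        sigma_e_mean=float(se_tr.mean()),
        sigma_b_mean=float(sb_tr.mean()),
        pi_samples=pi_tr if estimate_pi else None,
        n_samples=int(kept),
    )


def fit_bayesb(X_std, y, cfg: BayesConfig | None = None) -> BayesPosterior:
    """Mixture of a point mass (probability pi) and a scaled-t slab,
    with per-marker slab variances; pi is fixed."""
    return _run_gibbs(X_std, y, cfg or BayesConfig(), per_snp_var=True, estimate_pi=False)


def fit_bayescpi(X_std, y, cfg: BayesConfig | None = None, estimate_pi: bool = True) -> BayesPosterior:
    """Mixture of a point mass and a common-variance normal slab; pi is
    estimated under a uniform (0, 1) prior unless ``estimate_pi=False``."""
    return _run_gibbs(X_std, y, cfg or BayesConfig(), per_snp_var=False, estimate_pi=estimate_pi)


class _BayesRegressorBase(RegressorMixin, BaseEstimator):
    _per_snp_var: bool
    _estimate_pi: bool

    def __init__(self, n_iter=50_000, burn_in=20_000, thin=50, pi=0.95,
                 df_v=4.2, scale_S2=None, h2_prior=0.3, random_state=0):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.pi = pi
        self.df_v = df_v
        self.scale_S2 = scale_S2
        self.h2_prior = h2_prior
        self.random_state = random_state

    def _config(self) -> BayesConfig:
        return BayesConfig(
            n_iter=self.n_iter, burn_in=self.burn_in, thin=self.thin, pi=self.pi,
            df_v=self.df_v, scale_S2=self.scale_S2, h2_prior=self.h2_prior,
            seed=int(self.random_state or 0),
        )

    def fit(self, X, y):
        X = check_array(X, dtype=float)
        y = check_array(y, ensure_2d=False, dtype=float)
        self._x_mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance genotype column; run QC first")
        self._x_sd = sd
        X_std = (X - self._x_mean) / sd
        self.posterior_ = _run_gibbs(
            X_std, y, self._config(), self._per_snp_var, self._estimate_pi
        )
        self.beta_mean_ = self.posterior_.beta_mean
        self.beta_se_ = self.posterior_.beta_se
        self.mu_ = self.posterior_.mu_mean
        self.pi_mean_ = self.posterior_.pi_mean
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "posterior_")
        X = check_array(X, dtype=float)
        X_std = (X - self._x_mean) / self._x_sd
        return self.mu_ + X_std @ self.beta_mean_


class BayesBRegressor(_BayesRegressorBase):
    """Gibbs-sampled regression with fixed-pi point-mass + scaled-t prior."""

    _per_snp_var = True
    _estimate_pi = False


class BayesCPiRegressor(_BayesRegressorBase):
    """Gibbs-sampled regression with common normal slab and estimated pi."""

    _per_snp_var = False
    _estimate_pi = True
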