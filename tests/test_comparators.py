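"""GBLUP, Bayesian samplers and random forest: oracles and recovery."""

import numpy as np
import pytest
from scipy import stats

from banngp import (
    BayesConfig,
    GridSearchForestRegressor,
    SimArchitecture,
    build_grm,
    fit_bayesb,
    fit_bayescpi,
    fit_gblup,
    partition_by_window,
    predict_gblup,
    reliability_weights,
    simulate_genotypes,
    simulate_phenotypes,
    standardize,
)


class TestGRM:
    def test_hand_computed_toy(self):
        X = np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]])
        p = X.mean(axis=0) / 2.0
        W = X - 2 * p
        expected = W @ W.T / (2 * float((p * (1 - p)).sum()))
        np.testing.assert_allclose(build_grm(X), expected)

    def test_identical_individuals_share_rows(self):
        rng = np.random.default_rng(1)
        X = rng.binomial(2, 0.4, (6, 40)).astype(float)
        X[3] = X[0]
        G = build_grm(X)
        np.testing.assert_allclose(G[0], G[3])
        assert G[0, 0] == pytest.approx(G[0, 3])

    def test_vanraden_scaling_mean_diagonal_near_one(self):
        g = simulate_genotypes(2000, 400, 0.1, 0.5, 0.0, seed=2)
        G = build_grm(g.dosages)
        assert 0.95 <= float(np.diag(G).mean()) <= 1.05

    def test_monomorphic_rejected(self):
        X = np.column_stack([np.zeros(5), np.arange(5) % 3]).astype(float)
        with pytest.raises(ValueError, match="monomorphic"):
            build_grm(X)


def dense_blup_oracle(y, G, Ddiag, sg2, se2):
    """Direct dense solve: mu by GLS, g = sg2 G V^-1 (y - mu)."""
    n = len(y)
    V = sg2 * G + se2 * np.diag(Ddiag)
    Vi = np.linalg.inv(V)
    ones = np.ones(n)
    mu = float(ones @ Vi @ y) / float(ones @ Vi @ ones)
    return mu, sg2 * G @ Vi @ (y - mu)


class TestGBLUP:
    def _data(self, n=50, J=80, seed=0):
        g = simulate_genotypes(n, J, 0.1, 0.5, 0.2, seed=seed)
        G = build_grm(g.dosages)
        rng = np.random.default_rng(seed + 1)
        y = rng.multivariate_normal(np.zeros(n), 0.4 * G + 0.6 * np.eye(n))
        return G, y, rng

    def test_known_variance_solution_matches_dense_oracle(self):
        G, y, rng = self._data()
        Ddiag = rng.uniform(0.3, 2.0, len(y))
        model = fit_gblup(y, G, Ddiag, reml=False, sigma_g_sq=0.4, sigma_e_sq=0.6,
                          ridge=0.0)
        mu_o, g_o = dense_blup_oracle(y, G, Ddiag, 0.4, 0.6)
        assert model.mu == pytest.approx(mu_o, abs=1e-8)
        np.testing.assert_allclose(model.gebv, g_o, atol=1e-8)

    def test_reml_optimum_beats_likelihood_grid(self):
        """The fitted ratio attains the REML profile maximum found by a
        brute-force grid."""
        from banngp.gblup import _reml_profile

        G, y, _ = self._data(n=60, seed=3)
        Ddiag = np.ones(60)
        model = fit_gblup(y, G, Ddiag, reml=True)
        A = G + 1e-6 * np.eye(60)
        dvals, U = np.linalg.eigh(A)
        w = U.T @ y
        x = U.T @ np.ones(60)
        grid = np.linspace(-12, 12, 2001)
        best = min(_reml_profile(lg, np.clip(dvals, 0, None), w, x) for lg in grid)
        ours = _reml_profile(np.log(model.sigma_g_sq / model.sigma_e_sq),
                             np.clip(dvals, 0, None), w, x)
        assert ours <= best + 1e-6

    def test_null_trait_gives_near_zero_genetic_variance(self):
        fracs = []
        for seed in range(10):
            g = simulate_genotypes(1000, 300, 0.1, 0.5, 0.0, seed=100 + seed)
            G = build_grm(g.dosages)
            y = np.random.default_rng(200 + seed).standard_normal(1000)
            m = fit_gblup(y, G, reml=True)
            fracs.append(m.h2)
        assert np.mean(fracs) < 0.05
        assert sum(f < 0.05 for f in fracs) >= 9

    def test_prediction_matches_joint_conditional_oracle(self):
        G, y, rng = self._data(n=60, seed=5)
        Ddiag = rng.uniform(0.5, 1.5, 60)
        tr, te = np.arange(40), np.arange(40, 60)
        model = fit_gblup(y[tr], G[np.ix_(tr, tr)], Ddiag[tr], reml=False,
                          sigma_g_sq=0.4, sigma_e_sq=0.6, ridge=0.0)
        pred = predict_gblup(model, G, y[tr], tr, te, Ddiag[tr])
        # oracle: conditional mean of g_test given training records
        V = 0.4 * G[np.ix_(tr, tr)] + 0.6 * np.diag(Ddiag[tr])
        oracle = model.mu + 0.4 * G[np.ix_(te, tr)] @ np.linalg.solve(V, y[tr] - model.mu)
        np.testing.assert_allclose(pred, oracle, atol=1e-8)

    def test_infinite_shrinkage_predicts_the_mean(self):
        G, y, _ = self._data(n=40, seed=6)
        y = y - y.mean()
        tr, te = np.arange(30), np.arange(30, 40)
        model = fit_gblup(y[tr], G[np.ix_(tr, tr)], reml=False,
                          sigma_g_sq=1e-12, sigma_e_sq=1.0)
        pred = predict_gblup(model, G, y[tr], tr, te)
        np.testing.assert_allclose(pred - model.mu, np.zeros(10), atol=1e-6)

    def test_clone_of_training_animal_with_high_reliability(self):
        g = simulate_genotypes(60, 100, 0.1, 0.5, 0.0, seed=7)
        X = np.vstack([g.dosages, g.dosages[0]])  # animal 60 clones animal 0
        G = build_grm(X)
        rng = np.random.default_rng(8)
        y = rng.standard_normal(60)
        r2 = np.full(60, 0.999)
        model = fit_gblup(y, G[:60, :60], reliability_weights(r2), reml=False,
                          sigma_g_sq=0.5, sigma_e_sq=0.5)
        pred = predict_gblup(model, G, y, np.arange(60), np.array([60]),
                             reliability_weights(r2))
        assert pred[0] == pytest.approx(model.mu + model.gebv[0], abs=1e-6)

    def test_heritability_recovery(self):
        hits = 0
        for seed in range(10):
            g = simulate_genotypes(1000, 500, 0.05, 0.5, 0.2, chrom_count=2,
                                   seed=200 + seed)
            part = partition_by_window(g.variants)
            arch = SimArchitecture(pi_causal=0.2, epistasis_frac=0.0,
                                   h2_target=0.33, seed=300 + seed)
            y, _ = simulate_phenotypes(g, part, arch)
            m = fit_gblup(y, build_grm(g.dosages), reml=True)
            hits += 0.28 <= m.h2 <= 0.38
        assert hits >= 8


def t_slab_posterior_mean_by_quadrature(x, y, pi, nu, S2, se2):
    """Posterior mean of one effect under spike + scaled-t slab, by direct
    numerical integration (the slab is t with scale sqrt(S2) and nu df)."""
    d = float(x @ x)
    xy = float(x @ y)
    beta = np.linspace(-4, 4, 400_001)
    loglik = (2 * beta * xy - beta**2 * d) / (2 * se2)
    prior = stats.t.pdf(beta / np.sqrt(S2), df=nu) / np.sqrt(S2)
    w = (1 - pi) * prior * np.exp(loglik - loglik.max())
    cont_mass = np.trapezoid(w, beta)
    cont_mean = np.trapezoid(beta * w, beta)
    spike = pi * np.exp(-loglik.max())
    return cont_mean / (cont_mass + spike)


class TestBayes:
    def test_single_marker_matches_t_slab_quadrature(self):
        rng = np.random.default_rng(10)
        n = 500
        x = rng.standard_normal(n)
        x = (x - x.mean()) / x.std(ddof=1)
        y = 0.5 * x + rng.standard_normal(n) * 0.8
        cfg = BayesConfig(n_iter=30_000, burn_in=5_000, thin=5, pi=0.95,
                          df_v=4.2, scale_S2=0.05, fix_sigma_e=0.64, seed=11)
        post = fit_bayesb(x[:, None], y, cfg)
        oracle = t_slab_posterior_mean_by_quadrature(x, y, 0.95, 4.2, 0.05, 0.64)
        assert post.beta_mean[0] == pytest.approx(oracle, rel=0.1)

    def test_all_in_limit_matches_ridge_closed_form(self):
        """pi = 0 with pinned variances is Bayesian ridge regression."""
        rng = np.random.default_rng(12)
        n, J = 300, 20
        X = rng.standard_normal((n, J))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        beta_true = rng.standard_normal(J) * 0.3
        y = X @ beta_true + rng.standard_normal(n)
        y = y - y.mean()
        v, se2 = 0.1, 1.0
        cfg = BayesConfig(n_iter=20_000, burn_in=5_000, thin=5, pi=0.0,
                          fix_sigma_beta=v, fix_sigma_e=se2, seed=13)
        post = fit_bayescpi(X, y, cfg, estimate_pi=False)
        ridge = np.linalg.solve(X.T @ X + (se2 / v) * np.eye(J), X.T @ y)
        np.testing.assert_allclose(post.beta_mean, ridge, atol=0.04)
        assert np.all(post.incl_freq == 1.0)

    def test_large_effect_marker_always_included(self):
        rng = np.random.default_rng(14)
        n, J = 1000, 60
        X = rng.binomial(2, 0.4, (n, J)).astype(float)
        Xs, _, _ = standardize(X)
        y = Xs[:, 11] + rng.standard_normal(n)  # ~50% of variance
        cfg = BayesConfig(n_iter=5_000, burn_in=2_000, thin=10, seed=15)
        post = fit_bayesb(Xs, y, cfg)
        assert post.incl_freq[11] > 0.9

    def test_null_trait_inclusion_matches_prior(self):
        rng = np.random.default_rng(16)
        n, J = 500, 100
        X = rng.binomial(2, 0.3, (n, J)).astype(float)
        Xs, _, _ = standardize(X)
        y = rng.standard_normal(n)
        cfg = BayesConfig(n_iter=5_000, burn_in=2_000, thin=10, seed=17)
        post = fit_bayesb(Xs, y, cfg)
        assert post.incl_freq.mean() == pytest.approx(0.05, abs=0.03)

    def test_pi_chain_stays_in_unit_interval(self):
        rng = np.random.default_rng(18)
        X = rng.binomial(2, 0.3, (200, 50)).astype(float)
        Xs, _, _ = standardize(X)
        y = rng.standard_normal(200)
        cfg = BayesConfig(n_iter=2_000, burn_in=500, thin=5, seed=19)
        post = fit_bayescpi(Xs, y, cfg)
        assert np.all((post.pi_samples >= 0) & (post.pi_samples <= 1))
        assert post.beta_se.min() >= 0.0

    def test_chain_config_validation(self):
        with pytest.raises(ValueError):
            BayesConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            BayesConfig(thin=0)


class TestRandomForest:
    def test_chosen_hyperparameters_belong_to_grid(self):
        rng = np.random.default_rng(20)
        X = rng.binomial(2, 0.4, (120, 30)).astype(float)
        y = X[:, 0] - X[:, 5] + rng.standard_normal(120) * 0.5
        rf = GridSearchForestRegressor(grid_trees=(20, 50), grid_depth=(3, None),
                                       random_state=0)
        rf.fit(X, y)
        assert rf.best_params_["n_estimators"] in (20, 50)
        assert rf.best_params_["max_depth"] in (3, None)

    def test_pure_noise_does_not_pretend_to_fit(self):
        worst = []
        for seed in range(10):
            rng = np.random.default_rng(30 + seed)
            X = rng.binomial(2, 0.4, (150, 40)).astype(float)
            y = rng.standard_normal(150)
            rf = GridSearchForestRegressor(grid_trees=(30,), grid_depth=(3, None),
                                           random_state=seed)
            rf.fit(X, y)
            worst.append(rf.best_inner_mse_ / np.var(y, ddof=1))
        assert np.mean(worst) >= 0.9

    def test_step_function_capacity(self):
        rng = np.random.default_rng(40)
        X = rng.binomial(2, 0.5, (300, 10)).astype(float)
        y = (X[:, 3] >= 1).astype(float) * 2.0
        rf = GridSearchForestRegressor(grid_trees=(50,), grid_depth=(None,),
                                       random_state=1)
        rf.fit(X, y)
        resid = y - rf.predict(X)
        r2 = 1 - resid.var() / y.var()
        assert r2 > 0.9
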