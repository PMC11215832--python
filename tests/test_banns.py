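"""Two-layer annotated network: activations, variational inference,
oracle equivalence, PIP/PVE behavior, determinism."""

import numpy as np
import pytest

from banngp import (
    SimArchitecture,
    VEMConfig,
    build_hidden_inputs,
    estimate_pve,
    fit_banns,
    fit_set_layer,
    fit_snp_layer,
    leaky_relu,
    partition_by_window,
    posterior_inclusion_probabilities,
    predict,
    simulate_genotypes,
    simulate_phenotypes,
    standardize,
)
from banngp.snp_sets import SNPSet, SNPSetPartition


def mixture_posterior_mean_by_quadrature(x, y, pi, eta, sig2, tau2):
    """Exact posterior mean of a single-predictor spike/mixture-slab
    regression via numerical integration over the effect size."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    d = float(x @ x)
    xy = float(x @ y)
    beta = np.linspace(-5, 5, 200_001)
    loglik = (2 * beta * xy - beta**2 * d) / (2 * tau2)  # common term dropped
    prior = sum(
        e * np.exp(-(beta**2) / (2 * s)) / np.sqrt(2 * np.pi * s)
        for e, s in zip(eta, sig2)
    )
    w = pi * prior * np.exp(loglik - loglik.max())
    cont_mass = np.trapezoid(w, beta)
    cont_mean = np.trapezoid(beta * w, beta)
    spike_mass = (1 - pi) * np.exp(-loglik.max())
    return cont_mean / (cont_mass + spike_mass)


class TestActivationAndStandardize:
    def test_leaky_relu_values(self):
        assert leaky_relu(2.0) == 2.0
        assert leaky_relu(-1.0) == -0.01
        assert leaky_relu(0.0) == 0.0
        np.testing.assert_allclose(leaky_relu([3.0, -2.0]), [3.0, -0.02])

    def test_column_standardization_n_minus_1(self):
        X = np.array([[0.0], [1.0], [2.0]])
        Xs, ys, c = standardize(X, np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(Xs[:, 0], [-1.0, 0.0, 1.0])
        np.testing.assert_allclose(ys, [-1.0, 0.0, 1.0])

    def test_constant_trait_and_dead_column_errors(self):
        X = np.array([[0.0, 1.0], [1.0, 1.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="zero-variance"):
            standardize(X, np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError, match="constant"):
            standardize(X[:, :1], np.ones(3))

    def test_constants_round_trip(self):
        rng = np.random.default_rng(0)
        X = rng.binomial(2, 0.4, (30, 4)).astype(float)
        y = rng.standard_normal(30)
        Xs, ys, c = standardize(X, y)
        np.testing.assert_allclose(Xs * c["x_sd"] + c["x_mean"], X, atol=1e-12)
        np.testing.assert_allclose(ys * c["y_sd"] + c["y_mean"], y, atol=1e-12)


class TestHiddenInputs:
    def test_zero_weights_give_zero_columns(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((10, 6))
        part = SNPSetPartition(
            [SNPSet("a", "a", "window", (0, 1, 2)), SNPSet("b", "b", "window", (3, 4, 5))], 6
        )
        H = build_hidden_inputs(np.zeros(6), X, part)
        np.testing.assert_array_equal(H, np.zeros((10, 2)))

    def test_single_set_column_is_activated_score(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((15, 4))
        beta = rng.standard_normal(4)
        part = SNPSetPartition([SNPSet("all", "all", "window", (0, 1, 2, 3))], 4)
        H = build_hidden_inputs(beta, X, part)
        np.testing.assert_allclose(H[:, 0], leaky_relu(X @ beta))

    def test_hand_computed_toy(self):
        X = np.array([[1.0, -1.0], [0.0, 2.0], [-2.0, 1.0]])
        beta = np.array([0.5, 1.0])
        part = SNPSetPartition([SNPSet("s", "s", "window", (0, 1))], 2)
        H = build_hidden_inputs(beta, X, part)
        # scores: -0.5, 2.0, 0.0 -> leaky: -0.005, 2.0, 0.0
        np.testing.assert_allclose(H[:, 0], [-0.005, 2.0, 0.0])


class TestSNPLayer:
    def test_null_data_is_calibrated(self):
        """Pure-noise traits should not light up SNP inclusion."""
        means = []
        for seed in range(30):
            rng = np.random.default_rng(100 + seed)
            X = rng.binomial(2, 0.3, (500, 50)).astype(float)
            Xs, ys, _ = standardize(X, rng.standard_normal(500))
            means.append(fit_snp_layer(Xs, ys, VEMConfig(seed=seed)).pip.mean())
        assert np.mean(means) < 0.2

    def test_strong_single_signal_recovered(self):
        rng = np.random.default_rng(0)
        X = rng.binomial(2, 0.3, (1000, 50)).astype(float)
        Xs, _, _ = standardize(X)
        y = Xs[:, 7] + rng.standard_normal(1000)
        Xs, ys, _ = standardize(X, y)
        post = fit_snp_layer(Xs, ys, VEMConfig(seed=1))
        assert post.pip[7] > 0.95
        assert np.delete(post.pip, 7).mean() < 0.1
        assert post.eta_theta.sum() == pytest.approx(1.0)

    def test_single_predictor_matches_quadrature_oracle(self):
        """With hyperparameters pinned, the variational family contains the
        exact posterior, so the fit must agree with direct integration."""
        rng = np.random.default_rng(5)
        n = 400
        x = rng.standard_normal(n)
        x = (x - x.mean()) / x.std(ddof=1)
        y = 0.35 * x + rng.standard_normal(n) * 0.9
        y = (y - y.mean()) / y.std(ddof=1)
        pi, eta, sig2, tau2 = 0.3, np.array([0.2, 0.3, 0.5]), np.array([0.2, 0.05, 0.01]), 0.8
        oracle = mixture_posterior_mean_by_quadrature(x, y, pi, eta, sig2, tau2)
        cfg = VEMConfig(
            pi_grid=np.array([pi]), sigma_init=sig2, eta_init=eta, tau_init=tau2,
            update_sigma=False, update_eta=False, update_tau=False,
            init="zero", elbo_tol=1e-10,
        )
        post = fit_snp_layer(x[:, None], y, cfg)
        assert post.beta_theta[0] == pytest.approx(oracle, rel=0.05)


class TestSetLayer:
    def test_single_set_signal_recovered_and_null_calibrated(self):
        rng = np.random.default_rng(3)
        n, G = 600, 30
        H = rng.standard_normal((n, G))
        y = H[:, 4] * 0.8 + rng.standard_normal(n) * 0.6
        Hs, ys, _ = standardize(H, y)
        post = fit_set_layer(Hs, ys, VEMConfig(seed=2))
        assert post.gamma[4] > 0.9
        ynull = rng.standard_normal(n)
        Hs, ys, _ = standardize(H, ynull)
        post_null = fit_set_layer(Hs, ys, VEMConfig(seed=3))
        assert post_null.gamma.mean() < 0.2

    def test_single_neuron_matches_quadrature_oracle(self):
        rng = np.random.default_rng(6)
        n = 400
        h = rng.standard_normal(n)
        h = (h - h.mean()) / h.std(ddof=1)
        y = 0.4 * h + rng.standard_normal(n) * 0.8
        y = (y - y.mean()) / y.std(ddof=1)
        pi, sig2, tau2 = 0.4, 0.1, 0.7
        oracle = mixture_posterior_mean_by_quadrature(h, y, pi, [1.0], [sig2], tau2)
        cfg = VEMConfig(
            pi_grid=np.array([pi]), sigma_init=np.array([sig2]), tau_init=tau2,
            update_sigma=False, update_eta=False, update_tau=False,
            init="zero", elbo_tol=1e-10,
        )
        post = fit_set_layer(h[:, None], y, cfg)
        assert post.beta_w[0] == pytest.approx(oracle, rel=0.05)
        assert 0.0 <= post.gamma[0] <= 1.0


def _epistatic_fit(n=500, J=200, seed=0, **arch_kw):
    g = simulate_genotypes(n, J, 0.1, 0.5, 0.2, chrom_count=2, seed=seed)
    part = partition_by_window(g.variants)
    arch = SimArchitecture(seed=seed + 1000, **arch_kw)
    y, truth = simulate_phenotypes(g, part, arch)
    fit = fit_banns(g.dosages, y, part, VEMConfig(seed=seed))
    return g, part, y, truth, fit


class TestFullNetwork:
    def test_fixed_seed_is_bit_reproducible(self):
        g, part, y, _, fit1 = _epistatic_fit(n=200, J=80, seed=4, pi_causal=0.1)
        fit2 = fit_banns(g.dosages, y, part, VEMConfig(seed=4))
        np.testing.assert_array_equal(fit1.snp_layer.beta_theta, fit2.snp_layer.beta_theta)
        np.testing.assert_array_equal(fit1.set_layer.beta_w, fit2.set_layer.beta_w)
        np.testing.assert_array_equal(predict(fit1, g.dosages), predict(fit2, g.dosages))

    def test_elbo_monotone_within_each_grid_run(self):
        _, _, _, _, fit = _epistatic_fit(n=300, J=100, seed=5, pi_causal=0.1)
        for layer in ("snp", "set"):
            for trace in fit.elbo_trace[layer]:
                assert np.all(np.diff(trace) >= -1e-8)

    def test_predicting_training_set_reproduces_fitted_values(self):
        g, _, _, _, fit = _epistatic_fit(n=200, J=80, seed=6, pi_causal=0.1)
        np.testing.assert_allclose(predict(fit, g.dosages), fit.fitted_values)

    def test_duplicated_individual_identical_prediction(self):
        g, _, _, _, fit = _epistatic_fit(n=200, J=80, seed=7, pi_causal=0.1)
        pair = np.vstack([g.dosages[3], g.dosages[3]])
        pv = predict(fit, pair)
        assert pv[0] == pv[1]

    def test_zero_hidden_weights_predict_constant_bias(self):
        g, _, _, _, fit = _epistatic_fit(n=200, J=80, seed=8, pi_causal=0.1)
        fit.set_layer.beta_w[:] = 0.0
        pv = predict(fit, g.dosages[:10])
        np.testing.assert_allclose(pv, np.full(10, fit.b2))

    def test_snp_mismatch_rejected(self):
        g, _, _, _, fit = _epistatic_fit(n=100, J=40, seed=9, pi_causal=0.1)
        with pytest.raises(ValueError, match="SNPs"):
            predict(fit, g.dosages[:, :20])

    def test_pips_and_pves_within_unit_interval(self):
        _, _, _, _, fit = _epistatic_fit(n=300, J=120, seed=10, pi_causal=0.1,
                                         epistasis_frac=0.3, n_enriched_sets=8)
        pip_snp, pip_set = posterior_inclusion_probabilities(fit)
        assert np.all((pip_snp >= 0) & (pip_snp <= 1))
        assert np.all((pip_set >= 0) & (pip_set <= 1))
        pve = estimate_pve(fit)
        assert 0.0 <= pve.pve_snp <= 1.0
        assert 0.0 <= pve.pve_set <= 1.0

    def test_causal_sets_rank_above_null_sets_by_pip(self):
        wins = 0
        for seed in range(10):
            _, part, _, truth, fit = _epistatic_fit(
                n=600, J=200, seed=20 + seed,
                pi_causal=0.1, n_enriched_sets=6, h2_target=0.4,
            )
            _, pip_set = posterior_inclusion_probabilities(fit)
            causal = np.array([s.set_id in truth.causal_sets for s in part.sets])
            if pip_set[causal].mean() > pip_set[~causal].mean():
                wins += 1
        assert wins >= 8

    def test_parameter_recovery_of_snp_effects(self):
        """Correlation between fitted and true SNP effects on sparse data."""
        cors = []
        for seed in range(10):
            g = simulate_genotypes(2000, 300, 0.1, 0.5, 0.2, seed=40 + seed)
            part = partition_by_window(g.variants)
            arch = SimArchitecture(pi_causal=0.05, h2_target=0.4, seed=60 + seed)
            y, truth = simulate_phenotypes(g, part, arch)
            Xs, ys, _ = standardize(g.dosages, y)
            post = fit_snp_layer(Xs, ys, VEMConfig(seed=seed))
            cors.append(np.corrcoef(post.beta_theta, truth.beta_true)[0, 1])
        assert np.mean(cors) > 0.6
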