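"""Numba inner loops: variational coordinate ascent and single-site Gibbs.

These kernels carry the per-SNP sequential updates that dominate run time;
all statistical bookkeeping (ELBO, EM hyperparameter updates, posterior
summaries) stays in the calling modules.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def cavi_sweep(Xt, d, r, b, alpha, mu, s2, log_pi, log_1mpi, log_eta, sig2, tau2):
    """One full coordinate-ascent sweep of the spike/mixture-slab family.

    Xt is (J, n) C-contiguous; r is maintained as y - X @ b and updated in
    place along with b, alpha, mu and s2.
    """
    J, n = Xt.shape
    K = sig2.shape[0]
    lw = np.empty(K + 1)
    for j in range(J):
        xj = Xt[j]
        xr = np.dot(xj, r) + d[j] * b[j]
        lw[0] = log_1mpi
        for k in range(K):
            s2_jk = tau2 / (d[j] + tau2 / sig2[k])
            mu_jk = s2_jk * xr / tau2
            s2[j, k] = s2_jk
            mu[j, k] = mu_jk
            lw[k + 1] = (
                log_pi + log_eta[k]
                + 0.5 * np.log(s2_jk / sig2[k])
                + 0.5 * mu_jk * mu_jk / s2_jk
            )
        m = lw[0]
        for k in range(1, K + 1):
            if lw[k] > m:
                m = lw[k]
        tot = 0.0
        for k in range(K + 1):
            lw[k] = np.exp(lw[k] - m)
            tot += lw[k]
        newb = 0.0
        for k in range(K):
            a = lw[k + 1] / tot
            alpha[j, k] = a
            newb += a * mu[j, k]
        diff = b[j] - newb
        if diff != 0.0:
            for i in range(n):
                r[i] += xj[i] * diff
        b[j] = newb


@njit(cache=True)
def gibbs_core(
    Xt, d, y,
    n_iter, burn_in, thin,
    per_snp_var,       # True: BayesB-style per-SNP slab variance
    pi0, estimate_pi,  # pi = prior probability of NO effect
    nu, S2,
    fix_sigma_e, sigma_e_fixed,
    fix_sigma_b, sigma_b_fixed,
    seed,
):
    """Single-site Gibbs sampler for mixture-prior whole-genome regression.

    Returns accumulated posterior sums over the retained (post burn-in,
    thinned) samples plus scalar traces.
    """
    np.random.seed(seed)
    J, n = Xt.shape
    beta = np.zeros(J)
    sb2 = np.empty(J)
    base_var = sigma_b_fixed if fix_sigma_b else nu * S2 / max(nu - 2.0, 0.5)
    for j in range(J):
        sb2[j] = base_var
    sb2_common = base_var
    mu = 0.0
    for i in range(n):
        mu += y[i]
    mu /= n
    r = y - mu
    sigma_e2 = sigma_e_fixed if fix_sigma_e else max(np.dot(r, r) / n * 0.5, 1e-8)
    pi = pi0

    n_keep = 0
    for it in range(n_iter):
        if it >= burn_in and (it - burn_in) % thin == 0:
            n_keep += 1
    beta_sum = np.zeros(J)
    beta_sq = np.zeros(J)
    incl_sum = np.zeros(J)
    mu_trace = np.empty(n_keep)
    pi_trace = np.empty(n_keep)
    se_trace = np.empty(n_keep)
    sb_trace = np.empty(n_keep)

    kept = 0
    for it in range(n_iter):
        # intercept
        rbar = 0.0
        for i in range(n):
            rbar += r[i]
        rbar /= n
        mu_new = np.random.normal(mu + rbar, np.sqrt(sigma_e2 / n))
        shift = mu_new - mu
        for i in range(n):
            r[i] -= shift
        mu = mu_new

        m_in = 0
        ssb = 0.0
        for j in range(J):
            xj = Xt[j]
            xr = np.dot(xj, r) + d[j] * beta[j]
            v = sb2[j] if per_snp_var else sb2_common
            C = d[j] / sigma_e2 + 1.0 / v
            log_bf = -0.5 * np.log(v * C) + xr * xr / (2.0 * sigma_e2 * sigma_e2 * C)
            if pi <= 0.0:
                p_in = 1.0
            elif pi >= 1.0:
                p_in = 0.0
            else:
                log_odds = np.log((1.0 - pi) / pi) + log_bf
                if log_odds > 35.0:
                    p_in = 1.0
                elif log_odds < -35.0:
                    p_in = 0.0
                else:
                    p_in = 1.0 / (1.0 + np.exp(-log_odds))
            old = beta[j]
            take = np.random.random() < p_in
            if take:
                mean = (xr / sigma_e2) / C
                bnew = np.random.normal(mean, np.sqrt(1.0 / C))
                m_in += 1
                ssb += bnew * bnew
            else:
                bnew = 0.0
            diff = old - bnew
            if diff != 0.0:
                for i in range(n):
                    r[i] += xj[i] * diff
            beta[j] = bnew
            if per_snp_var and not fix_sigma_b:
                if take:
                    sb2[j] = (nu * S2 + bnew * bnew) / np.random.chisquare(nu + 1.0)
                else:
                    sb2[j] = nu * S2 / np.random.chisquare(nu)

        if (not per_snp_var) and (not fix_sigma_b):
            sb2_common = (nu * S2 + ssb) / np.random.chisquare(nu + m_in)
        if estimate_pi:
            pi = np.random.beta(J - m_in + 1.0, m_in + 1.0)
        if not fix_sigma_e:
            sigma_e2 = max(np.dot(r, r) / np.random.chisquare(n), 1e-12)

        if it >= burn_in and (it - burn_in) % thin == 0:
            for j in range(J):
                beta_sum[j] += beta[j]
                beta_sq[j] += beta[j] * beta[j]
                if beta[j] != 0.0:
                    incl_sum[j] += 1.0
            mu_trace[kept] = mu
            pi_trace[kept] = pi
            se_trace[kept] = sigma_e2
            if per_snp_var:
                sbm = 0.0
                for j in range(J):
                    sbm += sb2[j]
                sb_trace[kept] = sbm / J
            else:
                sb_trace[kept] = sb2_common
            kept += 1

    return beta_sum, beta_sq, incl_sum, mu_trace, pi_trace, se_trace, sb_trace, kept
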