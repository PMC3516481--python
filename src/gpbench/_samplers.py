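"""Numba-compiled Gibbs chains for the Bayesian linear whole-genome regressions.

All chains operate on a centered response; the intercept sampled here is
the deviation from the sample mean and is added back by the callers.
Scaled-inverse-chi-square convention: ``sigma2 ~ ScInvChi2(df, s)`` has
density proportional to ``sigma2^-(df/2+1) exp(-df*s/(2*sigma2))``, prior
mean ``df*s/(df-2)`` and posterior draw ``(df*s + SS)/chi2(df + k)``.
Single-site marker updates run in a fixed ``j = 1..p`` scan order.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["brr_chain", "bayesab_chain", "bl_chain"]


@njit(cache=True)
def _rinvgauss(mu: float, lam: float) -> float:
    # Michael, Schucany & Haas (1976)
    nu = np.random.standard_normal()
    z = nu * nu
    x = mu + mu * mu * z / (2.0 * lam) - (mu / (2.0 * lam)) * np.sqrt(
        4.0 * mu * lam * z + mu * mu * z * z
    )
    if x <= 0.0:
        x = 1e-12
    if np.random.random() <= mu / (mu + x):
        return x
    return mu * mu / x


@njit(cache=True)
def _n_keep(n_iter: int, burn_in: int, thin: int) -> int:
    return (n_iter - burn_in - 1) // thin + 1


@njit(cache=True)
def brr_chain(
    X, y, df_b, s_b, df_e, s_e,
    n_iter, burn_in, thin, seed,
    update_sb, sb0, update_se, se0,
):
    """Gibbs chain for Bayesian ridge regression on a centered response.

    Returns posterior means of (mu, beta, sigma_b2, sigma_e2) plus thinned
    post-burn-in traces of the two variance components.
    """
    np.random.seed(seed)
    n, p = X.shape
    v = np.empty(p)
    for j in range(p):
        v[j] = np.dot(X[:, j], X[:, j])
    beta = np.zeros(p)
    mu = 0.0
    sb = sb0
    se = se0
    e = y.copy()
    nk = _n_keep(n_iter, burn_in, thin)
    sb_trace = np.empty(nk)
    se_trace = np.empty(nk)
    beta_sum = np.zeros(p)
    mu_sum = 0.0
    sb_sum = 0.0
    se_sum = 0.0
    t = 0
    for it in range(n_iter):
        # intercept deviation
        rbar = 0.0
        for i in range(n):
            rbar += e[i]
        rbar = rbar / n + mu
        mu_new = rbar + np.random.standard_normal() * np.sqrt(se / n)
        d = mu - mu_new
        for i in range(n):
            e[i] += d
        mu = mu_new
        # marker effects, single site
        for j in range(p):
            if v[j] <= 0.0:
                beta[j] = 0.0
                continue
            bj = beta[j]
            rj = np.dot(X[:, j], e) + v[j] * bj
            c = v[j] / se + 1.0 / sb
            mean = (rj / se) / c
            bj_new = mean + np.random.standard_normal() / np.sqrt(c)
            db = bj - bj_new
            if db != 0.0:
                for i in range(n):
                    e[i] += X[i, j] * db
            beta[j] = bj_new
        if update_sb:
            ssb = 0.0
            for j in range(p):
                ssb += beta[j] * beta[j]
            sb = (df_b * s_b + ssb) / np.random.chisquare(df_b + p)
        if update_se:
            sse = 0.0
            for i in range(n):
                sse += e[i] * e[i]
            se = (df_e * s_e + sse) / np.random.chisquare(df_e + n)
        if it >= burn_in:
            beta_sum += beta
            mu_sum += mu
            sb_sum += sb
            se_sum += se
            if (it - burn_in) % thin == 0:
                sb_trace[t] = sb
                se_trace[t] = se
                t += 1
    m = n_iter - burn_in
    return mu_sum / m, beta_sum / m, sb_sum / m, se_sum / m, sb_trace[:t], se_trace[:t]


@njit(cache=True)
def bayesab_chain(
    X, y, pi, df_b, s_b, df_e, s_e, flat_se,
    n_iter, burn_in, thin, seed,
    update_sj, sj0, update_se, se0,
):
    """Gibbs chain for the mixture-prior regression (Bayes B; Bayes A when pi=0).

    The indicator is sampled jointly with the effect, with the effect
    integrated out of the indicator's conditional odds (exact two-component
    Gibbs).  Per-marker variances follow ScInvChi2(df_b, s_b); excluded
    markers redraw theirs from the prior.  With ``flat_se`` the residual
    variance uses the improper flat prior (draw ``RSS / chi2(n - 2)``).
    """
    np.random.seed(seed)
    n, p = X.shape
    v = np.empty(p)
    for j in range(p):
        v[j] = np.dot(X[:, j], X[:, j])
    beta = np.zeros(p)
    sigma_j = sj0.copy()
    mu = 0.0
    se = se0
    e = y.copy()
    nk = _n_keep(n_iter, burn_in, thin)
    se_trace = np.empty(nk)
    beta_sum = np.zeros(p)
    incl_sum = np.zeros(p)
    sj_sum = np.zeros(p)
    mu_sum = 0.0
    se_sum = 0.0
    t = 0
    log_prior_odds = 0.0
    if pi > 0.0:
        log_prior_odds = np.log(1.0 - pi) - np.log(pi)
    for it in range(n_iter):
        rbar = 0.0
        for i in range(n):
            rbar += e[i]
        rbar = rbar / n + mu
        mu_new = rbar + np.random.standard_normal() * np.sqrt(se / n)
        d = mu - mu_new
        for i in range(n):
            e[i] += d
        mu = mu_new
        for j in range(p):
            if v[j] <= 0.0:
                beta[j] = 0.0
                continue
            bj = beta[j]
            rj = np.dot(X[:, j], e) + v[j] * bj
            sj = sigma_j[j]
            if pi <= 0.0:
                inc = True
            else:
                denom = v[j] * sj + se
                log_bf = 0.5 * np.log(se / denom) + 0.5 * rj * rj * sj / (se * denom)
                lo = log_prior_odds + log_bf
                if lo > 35.0:
                    inc = True
                elif lo < -35.0:
                    inc = False
                else:
                    inc = np.random.random() < 1.0 / (1.0 + np.exp(-lo))
            if inc:
                c = v[j] / se + 1.0 / sj
                mean = (rj / se) / c
                bj_new = mean + np.random.standard_normal() / np.sqrt(c)
            else:
                bj_new = 0.0
            db = bj - bj_new
            if db != 0.0:
                for i in range(n):
                    e[i] += X[i, j] * db
            beta[j] = bj_new
            if update_sj:
                if inc:
                    sigma_j[j] = (df_b * s_b + bj_new * bj_new) / np.random.chisquare(df_b + 1.0)
                else:
                    sigma_j[j] = (df_b * s_b) / np.random.chisquare(df_b)
            if it >= burn_in and inc:
                incl_sum[j] += 1.0
        if update_se:
            sse = 0.0
            for i in range(n):
                sse += e[i] * e[i]
            if flat_se:
                se = sse / np.random.chisquare(n - 2.0)
            else:
                se = (df_e * s_e + sse) / np.random.chisquare(df_e + n)
        if it >= burn_in:
            beta_sum += beta
            sj_sum += sigma_j
            mu_sum += mu
            se_sum += se
            if (it - burn_in) % thin == 0:
                se_trace[t] = se
                t += 1
    m = n_iter - burn_in
    return (
        mu_sum / m,
        beta_sum / m,
        sj_sum / m,
        se_sum / m,
        incl_sum / m,
        se_trace[:t],
    )


@njit(cache=True)
def bl_chain(
    X, y, lam2_shape, lam2_rate, df_e, s_e,
    n_iter, burn_in, thin, seed,
    update_tau, tau0, update_lam, lam2_0, update_se, se0,
):
    """Gibbs chain for the Bayesian LASSO via the normal-exponential mixture.

    ``beta_j | tau_j^2, sigma_e^2 ~ N(0, tau_j^2 sigma_e^2)``; ``1/tau_j^2``
    has an inverse-Gaussian full conditional, ``lambda^2`` a Gamma full
    conditional under a Gamma(shape, rate) prior, and ``sigma_e^2`` a
    scaled-inverse-chi-square conditional that pools the residual sum of
    squares with ``sum beta_j^2 / tau_j^2``.
    """
    np.random.seed(seed)
    n, p = X.shape
    v = np.empty(p)
    for j in range(p):
        v[j] = np.dot(X[:, j], X[:, j])
    beta = np.zeros(p)
    tau2 = tau0.copy()
    lam2 = lam2_0
    mu = 0.0
    se = se0
    e = y.copy()
    nk = _n_keep(n_iter, burn_in, thin)
    se_trace = np.empty(nk)
    lam2_trace = np.empty(nk)
    beta_sum = np.zeros(p)
    tau2_sum = np.zeros(p)
    mu_sum = 0.0
    se_sum = 0.0
    lam2_sum = 0.0
    t = 0
    for it in range(n_iter):
        rbar = 0.0
        for i in range(n):
            rbar += e[i]
        rbar = rbar / n + mu
        mu_new = rbar + np.random.standard_normal() * np.sqrt(se / n)
        d = mu - mu_new
        for i in range(n):
            e[i] += d
        mu = mu_new
        for j in range(p):
            if v[j] <= 0.0:
                beta[j] = 0.0
                continue
            bj = beta[j]
            rj = np.dot(X[:, j], e) + v[j] * bj
            prec = (v[j] + 1.0 / tau2[j]) / se
            mean = (rj / se) / prec
            bj_new = mean + np.random.standard_normal() / np.sqrt(prec)
            db = bj - bj_new
            if db != 0.0:
                for i in range(n):
                    e[i] += X[i, j] * db
            beta[j] = bj_new
        if update_tau:
            for j in range(p):
                b2 = beta[j] * beta[j]
                if b2 < 1e-14:
                    b2 = 1e-14
                mu_ig = np.sqrt(lam2 * se / b2)
                if mu_ig > 1e8:
                    mu_ig = 1e8
                inv_tau2 = _rinvgauss(mu_ig, lam2)
                tau2[j] = 1.0 / inv_tau2
        if update_lam:
            rate = lam2_rate
            for j in range(p):
                rate += tau2[j] / 2.0
            lam2 = np.random.gamma(lam2_shape + p, 1.0 / rate)
        if update_se:
            sse = 0.0
            for i in range(n):
                sse += e[i] * e[i]
            ssb = 0.0
            for j in range(p):
                ssb += beta[j] * beta[j] / tau2[j]
            se = (df_e * s_e + sse + ssb) / np.random.chisquare(df_e + n + p)
        if it >= burn_in:
            beta_sum += beta
            tau2_sum += tau2
            mu_sum += mu
            se_sum += se
            lam2_sum += lam2
            if (it - burn_in) % thin == 0:
                se_trace[t] = se
                lam2_trace[t] = lam2
                t += 1
    m = n_iter - burn_in
    return (
        mu_sum / m,
        beta_sum / m,
        tau2_sum / m,
        se_sum / m,
        lam2_sum / m,
        se_trace[:t],
        lam2_trace[:t],
    )
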