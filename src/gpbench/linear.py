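"""Bayesian linear whole-genome regressions: BRR, Bayesian LASSO, Bayes A/B.

All four models share the likelihood ``y_i = mu + sum_j x_ij beta_j + e_i``
with Gaussian residuals and differ only in the prior placed on the marker
effects:

* BRR: ``beta_j ~ N(0, sigma_b2)`` with a common variance, scaled-inverse-
  chi-square priors (df=4, s=1 defaults) on both variance components;
* Bayesian LASSO: double-exponential prior via the normal-exponential
  scale mixture, Gamma hyperprior on ``lambda^2``;
* Bayes B: point mass at zero with probability ``pi`` (default 0.95) mixed
  with ``N(0, sigma_j2)``, per-marker variances ScInvChi2(df_b=4, s_b)
  where ``s_b`` derives from allele frequencies; flat prior on the residual
  variance.  Bayes A is Bayes B with ``pi = 0``.

The response is centered internally; the reported intercept is on the
original scale.  Markers are used as given (0/1 dominant calls, no
standardization).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gpbench import _samplers
from gpbench.io import GenotypeMatrix

__all__ = [
    "LinearPriors",
    "MCMCSettings",
    "LinearFit",
    "bayesb_scale_hyperparameter",
    "fit_brr",
    "fit_bayesian_lasso",
    "fit_bayes_a",
    "fit_bayes_b",
    "predict_linear",
]


@dataclass
class MCMCSettings:
    """Chain length controls; defaults follow the benchmarking protocol."""

    n_iter: int = 35_000
    burn_in: int = 5_000
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("require 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class LinearPriors:
    """Prior hyperparameters for the linear models.

    Only the block relevant to the model being fitted is consulted.  For
    Bayes A/B, ``s_beta`` may be left ``None`` to be derived from allele
    frequencies through :func:`bayesb_scale_hyperparameter` with
    ``sigma_S2`` defaulting to half the training phenotypic variance.
    """

    # BRR
    df_beta: float = 4.0
    s_beta: float | None = 1.0
    df_e: float = 4.0
    s_e: float = 1.0
    # Bayes A/B
    pi: float = 0.95
    sigma_S2: float | None = None
    sigma_e2_prior: str = "flat"           # {"flat", "scaled_inv_chi2"}
    # Bayesian LASSO
    lambda2_shape: float = 0.55
    lambda2_rate: float = 1e-4

    def __post_init__(self) -> None:
        if self.df_beta <= 0 or self.df_e <= 0:
            raise ValueError("degrees of freedom must be positive")
        if not (0.0 <= self.pi < 1.0):
            raise ValueError("pi must be in [0, 1)")
        if self.s_beta is not None and self.s_beta <= 0:
            raise ValueError("s_beta must be positive")
        if self.sigma_e2_prior not in ("flat", "scaled_inv_chi2"):
            raise ValueError("sigma_e2_prior must be 'flat' or 'scaled_inv_chi2'")


@dataclass
class LinearFit:
    """Posterior summaries of a fitted linear whole-genome regression."""

    model: str
    mu_hat: float
    beta_hat: np.ndarray
    var_components: dict = field(default_factory=dict)
    inclusion_prob: np.ndarray | None = None
    fitted: np.ndarray | None = None
    marker_ids: list[str] | None = None
    traces: dict = field(default_factory=dict)

    def summary(self) -> dict:
        out = {
            "model": self.model,
            "mu_hat": float(self.mu_hat),
            "var_components": {
                k: (float(v) if np.ndim(v) == 0 else np.asarray(v).tolist())
                for k, v in self.var_components.items()
            },
            "n_markers": int(self.beta_hat.size),
        }
        if self.inclusion_prob is not None:
            out["mean_inclusion_prob"] = float(np.mean(self.inclusion_prob))
        return out


def _as_matrix(G) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(G, GenotypeMatrix):
        if not G.is_imputed:
            raise ValueError("genotypes contain missing values; run impute_and_prepare first")
        return np.asfortranarray(G.X, dtype=float), list(G.marker_ids)
    X = np.asfortranarray(np.asarray(G, dtype=float))
    if np.isnan(X).any():
        raise ValueError("genotype array contains NaN")
    return X, None


def _validate_training(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != X.shape[0]:
        raise ValueError("y length does not match number of lines")
    if not np.isfinite(y).all():
        raise ValueError("y contains non-finite values")
    if y.shape[0] < 2:
        raise ValueError("need at least 2 training lines")
    if np.ptp(y) == 0.0:
        raise ValueError("constant y: zero phenotypic variance")
    if X.shape[1] < 1:
        raise ValueError("need at least one marker")
    return y


def bayesb_scale_hyperparameter(
    q: np.ndarray, pi: float, df_beta: float, sigma_S2: float
) -> float:
    """Scale ``s_beta`` of the per-marker variance prior from allele frequencies.

    ``s_beta = sigma_a2 * (df_beta - 2) / df_beta`` with
    ``sigma_a2 = sigma_S2 / ((1 - pi) * sum_j 2 q_j (1 - q_j))``, where
    ``sigma_S2`` is the additive genetic variance explained by markers.
    """
    q = np.asarray(q, dtype=float)
    if df_beta <= 2.0:
        raise ValueError("df_beta must exceed 2 for the scale formula")
    if not (0.0 <= pi < 1.0):
        raise ValueError("pi must be in [0, 1)")
    if ((q <= 0.0) | (q >= 1.0)).any():
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    het = float(np.sum(2.0 * q * (1.0 - q)))
    if het <= 0.0:
        raise ValueError("sum of 2q(1-q) is zero; no marker variance")
    sigma_a2 = sigma_S2 / ((1.0 - pi) * het)
    return sigma_a2 * (df_beta - 2.0) / df_beta


def fit_brr(
    G,
    y,
    priors: LinearPriors | None = None,
    mcmc: MCMCSettings | None = None,
    update_sigma_beta: bool = True,
    update_sigma_e: bool = True,
    sigma_beta2_init: float | None = None,
    sigma_e2_init: float | None = None,
) -> LinearFit:
    """Fit Bayesian ridge regression by single-site Gibbs sampling.

    ``update_sigma_beta`` / ``update_sigma_e`` can be switched off (with the
    corresponding ``*_init`` fixed values) to reduce the sampler to its
    conditionally conjugate core, whose posterior mean of ``beta`` has the
    ridge closed form -- the main correctness oracle.
    """
    priors = priors or LinearPriors()
    mcmc = mcmc or MCMCSettings()
    X, marker_ids = _as_matrix(G)
    y = _validate_training(X, y)
    ybar = float(y.mean())
    yc = y - ybar
    vy = float(yc.var())
    s_b = priors.s_beta if priors.s_beta is not None else 1.0
    sb0 = sigma_beta2_init if sigma_beta2_init is not None else max(vy / (2.0 * X.shape[1]), 1e-8)
    se0 = sigma_e2_init if sigma_e2_init is not None else max(vy / 2.0, 1e-8)
    mu_c, beta, sb, se, sb_trace, se_trace = _samplers.brr_chain(
        X, yc, float(priors.df_beta), float(s_b), float(priors.df_e), float(priors.s_e),
        int(mcmc.n_iter), int(mcmc.burn_in), int(mcmc.thin), int(mcmc.seed) & 0xFFFFFFFF,
        bool(update_sigma_beta), float(sb0), bool(update_sigma_e), float(se0),
    )
    mu_hat = ybar + mu_c
    fitted = mu_hat + X @ beta
    return LinearFit(
        model="brr",
        mu_hat=mu_hat,
        beta_hat=beta,
        var_components={"sigma_e2": se, "sigma_beta2": sb},
        fitted=fitted,
        marker_ids=marker_ids,
        traces={"sigma_e2": se_trace, "sigma_beta2": sb_trace},
    )


def fit_bayesian_lasso(
    G,
    y,
    priors: LinearPriors | None = None,
    mcmc: MCMCSettings | None = None,
    update_tau: bool = True,
    update_lambda: bool = True,
    update_sigma_e: bool = True,
    tau2_init: np.ndarray | None = None,
    lambda2_init: float | None = None,
    sigma_e2_init: float | None = None,
) -> LinearFit:
    """Fit the Bayesian LASSO via its normal-exponential scale mixture."""
    priors = priors or LinearPriors()
    mcmc = mcmc or MCMCSettings()
    X, marker_ids = _as_matrix(G)
    y = _validate_training(X, y)
    p = X.shape[1]
    ybar = float(y.mean())
    yc = y - ybar
    vy = float(yc.var())
    tau0 = (
        np.asarray(tau2_init, dtype=float).copy()
        if tau2_init is not None
        else np.full(p, 1.0)
    )
    if tau0.shape != (p,):
        raise ValueError("tau2_init must have one entry per marker")
    lam2_0 = lambda2_init if lambda2_init is not None else float(2.0 * p)
    se0 = sigma_e2_init if sigma_e2_init is not None else max(vy / 2.0, 1e-8)
    mu_c, beta, tau2, se, lam2, se_trace, lam2_trace = _samplers.bl_chain(
        X, yc, float(priors.lambda2_shape), float(priors.lambda2_rate),
        float(priors.df_e), float(priors.s_e),
        int(mcmc.n_iter), int(mcmc.burn_in), int(mcmc.thin), int(mcmc.seed) & 0xFFFFFFFF,
        bool(update_tau), tau0, bool(update_lambda), float(lam2_0),
        bool(update_sigma_e), float(se0),
    )
    mu_hat = ybar + mu_c
    fitted = mu_hat + X @ beta
    return LinearFit(
        model="bl",
        mu_hat=mu_hat,
        beta_hat=beta,
        var_components={"sigma_e2": se, "tau2": tau2, "lambda2": lam2},
        fitted=fitted,
        marker_ids=marker_ids,
        traces={"sigma_e2": se_trace, "lambda2": lam2_trace},
    )


def fit_bayes_b(
    G,
    y,
    priors: LinearPriors | None = None,
    mcmc: MCMCSettings | None = None,
    pi: float | None = None,
    update_sigma_j: bool = True,
    update_sigma_e: bool = True,
    sigma_j2_init: np.ndarray | None = None,
    sigma_e2_init: float | None = None,
) -> LinearFit:
    """Fit Bayes B (mixture prior with mass ``pi`` at zero; Bayes A when pi=0).

    ``s_beta`` is taken from ``priors`` when set, otherwise derived from the
    training allele frequencies via :func:`bayesb_scale_hyperparameter`
    with ``sigma_S2`` defaulting to half the phenotypic variance.
    """
    priors = priors or LinearPriors(s_beta=None)
    mcmc = mcmc or MCMCSettings()
    X, marker_ids = _as_matrix(G)
    y = _validate_training(X, y)
    n, p = X.shape
    pi_val = priors.pi if pi is None else float(pi)
    if not (0.0 <= pi_val < 1.0):
        raise ValueError("pi must be in [0, 1)")
    flat_se = priors.sigma_e2_prior == "flat"
    if flat_se and n <= 4:
        raise ValueError("flat sigma_e2 prior requires n_train > 4")
    ybar = float(y.mean())
    yc = y - ybar
    vy = float(yc.var())
    if priors.s_beta is not None:
        s_b = float(priors.s_beta)
    else:
        q = X.mean(axis=0)
        poly = (q > 0.0) & (q < 1.0)
        if not poly.any():
            raise ValueError("all markers monomorphic in training data")
        sigma_S2 = priors.sigma_S2 if priors.sigma_S2 is not None else 0.5 * vy
        s_b = bayesb_scale_hyperparameter(q[poly], pi_val, priors.df_beta, sigma_S2)
    sj0 = (
        np.asarray(sigma_j2_init, dtype=float).copy()
        if sigma_j2_init is not None
        else np.full(p, max(s_b, 1e-10) * priors.df_beta / max(priors.df_beta - 2.0, 1e-8))
    )
    if sj0.shape != (p,):
        raise ValueError("sigma_j2_init must have one entry per marker")
    se0 = sigma_e2_init if sigma_e2_init is not None else max(vy / 2.0, 1e-8)
    mu_c, beta, sigma_j, se, incl, se_trace = _samplers.bayesab_chain(
        X, yc, float(pi_val), float(priors.df_beta), float(s_b),
        float(priors.df_e), float(priors.s_e), bool(flat_se),
        int(mcmc.n_iter), int(mcmc.burn_in), int(mcmc.thin), int(mcmc.seed) & 0xFFFFFFFF,
        bool(update_sigma_j), sj0, bool(update_sigma_e), float(se0),
    )
    mu_hat = ybar + mu_c
    fitted = mu_hat + X @ beta
    return LinearFit(
        model="bayesa" if pi_val == 0.0 else "bayesb",
        mu_hat=mu_hat,
        beta_hat=beta,
        var_components={"sigma_e2": se, "sigma_j2": sigma_j, "s_beta": s_b},
        inclusion_prob=incl,
        fitted=fitted,
        marker_ids=marker_ids,
        traces={"sigma_e2": se_trace},
    )


def fit_bayes_a(G, y, priors: LinearPriors | None = None, mcmc: MCMCSettings | None = None, **kw) -> LinearFit:
    """Bayes A: the ``pi = 0`` code path of :func:`fit_bayes_b`."""
    return fit_bayes_b(G, y, priors=priors, mcmc=mcmc, pi=0.0, **kw)


def _align_new(fit_marker_ids, G_new) -> np.ndarray:
    if isinstance(G_new, GenotypeMatrix):
        if not G_new.is_imputed:
            raise ValueError("genotypes contain missing values; run impute_and_prepare first")
        if fit_marker_ids is not None:
            pos = {m: j for j, m in enumerate(G_new.marker_ids)}
            missing = [m for m in fit_marker_ids if m not in pos]
            if missing:
                raise ValueError(f"markers absent from new genotypes: {missing[:10]}")
            cols = [pos[m] for m in fit_marker_ids]
            return G_new.X[:, cols]
        return G_new.X
    X = np.asarray(G_new, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    return X


def predict_linear(fit: LinearFit, G_new) -> np.ndarray:
    """Predict ``mu_hat + X_new @ beta_hat`` with marker-id alignment."""
    X = _align_new(fit.marker_ids, G_new)
    if X.shape[1] != fit.beta_hat.size:
        raise ValueError(
            f"marker count mismatch: fit has {fit.beta_hat.size}, new data has {X.shape[1]}"
        )
    return fit.mu_hat + X @ fit.beta_hat
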