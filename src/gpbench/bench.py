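"""Cross-validation benchmarking: metrics, paired testing, heritability, reports.

The driver builds one list of random 90/10 partitions, reuses it for every
model being compared (so per-partition correlations are paired), and
aggregates Pearson correlation and predictive mean-squared error per
(model, trait, environment).  "SE" in the report is the standard deviation
of the per-partition correlations, matching the magnitudes the comparison
protocol prints; set ``se_mode="sem"`` for SD/sqrt(n) instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from gpbench.io import CVPartition, GenotypeMatrix, PhenotypeTable, RunConfig, derive_stream_seed, make_partitions
from gpbench.linear import (
    LinearPriors,
    MCMCSettings,
    fit_bayes_a,
    fit_bayes_b,
    fit_bayesian_lasso,
    fit_brr,
    predict_linear,
)
from gpbench.neural import TrainGrid, predict_network, train_brnn, train_rbfnn
from gpbench.rkhs import KernelSpec, fit_rkhs, predict_rkhs

logger = logging.getLogger(__name__)

__all__ = [
    "MetricRow",
    "HeritabilityInput",
    "pearson_correlation",
    "pmse",
    "paired_t_test",
    "cross_validate",
    "heritability_single_env",
    "heritability_combined",
    "summarize_benchmark",
    "MODEL_NAMES",
    "make_model_runner",
]


@dataclass
class MetricRow:
    """Aggregated cross-validation metrics for one (model, trait, env) cell."""

    model: str
    trait: str
    env: str
    mean_corr: float
    se_corr: float
    mean_pmse: float
    n_partitions: int
    per_partition_corr: np.ndarray = field(default_factory=lambda: np.zeros(0))
    per_partition_pmse: np.ndarray = field(default_factory=lambda: np.zeros(0))
    n_failed: int = 0


@dataclass
class HeritabilityInput:
    """Variance components for the combined-analysis heritability formula."""

    sigma_g2: float
    sigma_ge2: float
    sigma_e2: float
    nreps: int = 1
    nenv: int = 1

    def __post_init__(self) -> None:
        if min(self.sigma_g2, self.sigma_ge2, self.sigma_e2) < 0:
            raise ValueError("variance components must be nonnegative")
        if self.sigma_g2 + self.sigma_ge2 + self.sigma_e2 <= 0:
            raise ValueError("at least one variance component must be positive")
        if self.nreps < 1 or self.nenv < 1:
            raise ValueError("nreps and nenv must be >= 1")


def pearson_correlation(a, b) -> float:
    """Product-moment correlation; ``nan`` when either input is constant."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("length mismatch")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    ac = a - a.mean()
    bc = b - b.mean()
    sa = float(np.max(np.abs(ac)))
    sb = float(np.max(np.abs(bc)))
    if sa == 0.0 or sb == 0.0:
        return float("nan")
    ac = ac / sa        # pre-scale so squaring cannot under/overflow
    bc = bc / sb
    va = float(ac @ ac)
    vb = float(bc @ bc)
    if va == 0.0 or vb == 0.0:
        return float("nan")
    r = float(ac @ bc / np.sqrt(va * vb))
    return float(np.clip(r, -1.0, 1.0))


def pmse(obs, pred) -> float:
    """Predictive mean-squared error, ``mean((obs - pred)^2)``."""
    obs = np.asarray(obs, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    if obs.size != pred.size:
        raise ValueError("length mismatch")
    if obs.size < 1:
        raise ValueError("empty input")
    return float(np.mean((obs - pred) ** 2))


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    significant: bool
    df: int


def paired_t_test(corr_a, corr_b, alpha: float = 0.05) -> TTestResult:
    """Two-sided paired t-test on per-partition metric differences.

    Pairs with a missing value on either side are dropped.  Zero-variance
    differences yield the ``p = 1`` convention (t = 0).
    """
    a = np.asarray(corr_a, dtype=float).ravel()
    b = np.asarray(corr_b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("vectors must share the same partitions")
    ok = np.isfinite(a) & np.isfinite(b)
    d = a[ok] - b[ok]
    n = d.size
    if n < 3:
        raise ValueError("need at least 3 paired values")
    sd = d.std(ddof=1)
    if sd == 0.0:
        return TTestResult(t=0.0, p=1.0, significant=False, df=n - 1)
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return TTestResult(t=t, p=p, significant=p < alpha, df=n - 1)


def heritability_single_env(sigma_g2: float, sigma_e2: float, nreps: int = 1) -> float:
    """Entry-mean broad-sense heritability, ``sg2 / (sg2 + se2/nreps)``."""
    if sigma_g2 < 0 or sigma_e2 < 0:
        raise ValueError("variance components must be nonnegative")
    if nreps < 1:
        raise ValueError("nreps must be >= 1")
    denom = sigma_g2 + sigma_e2 / nreps
    if denom == 0:
        raise ValueError("zero denominator: all variance components zero")
    return sigma_g2 / denom


def heritability_combined(inp: HeritabilityInput) -> float:
    """``sg2 / (sg2 + sge2/nenv + se2/(nenv*nreps))`` across environments."""
    denom = inp.sigma_g2 + inp.sigma_ge2 / inp.nenv + inp.sigma_e2 / (inp.nenv * inp.nreps)
    if denom == 0:
        raise ValueError("zero denominator")
    return inp.sigma_g2 / denom


# ---------------------------------------------------------------------------
# model registry
# ---------------------------------------------------------------------------

MODEL_NAMES = ("brr", "bl", "bayesa", "bayesb", "rkhs", "rbfnn", "brnn")

Runner = Callable[[np.ndarray, np.ndarray, np.ndarray, int], np.ndarray]


def make_model_runner(name: str, config: RunConfig | None = None) -> Runner:
    """Build a ``(X_train, y_train, X_test, seed) -> predictions`` callable.

    Per-model options come from ``config.model_options[name]`` and are
    forwarded to the underlying fit functions (e.g. prior settings, kernel
    grid, neuron count).
    """
    config = config or RunConfig()
    opts = dict(config.model_options.get(name, {}))

    def mcmc(seed: int) -> MCMCSettings:
        return MCMCSettings(
            n_iter=opts.get("n_iter", config.n_iter),
            burn_in=opts.get("burn_in", config.burn_in),
            thin=opts.get("thin", config.thin),
            seed=seed,
        )

    if name == "brr":
        priors = LinearPriors(**opts.get("priors", {}))

        def run(Xtr, ytr, Xte, seed):
            fit = fit_brr(Xtr, ytr, priors=priors, mcmc=mcmc(seed))
            return predict_linear(fit, Xte)

    elif name == "bl":
        priors = LinearPriors(**opts.get("priors", {}))

        def run(Xtr, ytr, Xte, seed):
            fit = fit_bayesian_lasso(Xtr, ytr, priors=priors, mcmc=mcmc(seed))
            return predict_linear(fit, Xte)

    elif name in ("bayesa", "bayesb"):
        prior_kw = dict(opts.get("priors", {}))
        prior_kw.setdefault("s_beta", None)
        priors = LinearPriors(**prior_kw)
        fitter = fit_bayes_a if name == "bayesa" else fit_bayes_b

        def run(Xtr, ytr, Xte, seed):
            fit = fitter(Xtr, ytr, priors=priors, mcmc=mcmc(seed))
            return predict_linear(fit, Xte)

    elif name == "rkhs":
        spec = KernelSpec(**opts["kernel"]) if "kernel" in opts else None

        def run(Xtr, ytr, Xte, seed):
            fit = fit_rkhs(Xtr, ytr, spec=spec, mcmc=mcmc(seed))
            return predict_rkhs(fit, Xte)

    elif name == "rbfnn":
        grid = TrainGrid(**opts["grid"]) if "grid" in opts else TrainGrid()

        def run(Xtr, ytr, Xte, seed):
            net = train_rbfnn(Xtr, ytr, grid=grid, seed=seed)
            return predict_network(net, Xte)

    elif name == "brnn":
        brnn_kw = {
            k: opts[k]
            for k in ("S", "max_iter", "tol", "restarts", "alpha0", "beta0")
            if k in opts
        }

        def run(Xtr, ytr, Xte, seed):
            net = train_brnn(Xtr, ytr, seed=seed, **brnn_kw)
            return predict_network(net, Xte)

    else:
        raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")

    return run


def cross_validate(
    models: Sequence[str] | Mapping[str, Runner],
    G: GenotypeMatrix,
    pheno: PhenotypeTable,
    trait: str,
    env: str,
    config: RunConfig | None = None,
    partitions: list[CVPartition] | None = None,
) -> list[MetricRow]:
    """Benchmark models on one trait/environment over shared random partitions.

    Returns one :class:`MetricRow` per model.  A model failure on a
    partition is logged and that partition is excluded from the model's
    aggregates (its per-partition entry is ``nan``, which the paired t-test
    drops pairwise).
    """
    config = config or RunConfig()
    if isinstance(models, Mapping):
        runners = dict(models)
    else:
        if not models:
            raise ValueError("need at least one model")
        runners = {name: make_model_runner(name, config) for name in models}

    records = pheno.select(trait, env)
    pheno.check_lines(G)
    pos = {lid: i for i, lid in enumerate(G.line_ids)}
    rows = np.array([pos[lid] for lid in records["line_id"]])
    X_all = G.X[rows]
    y_all = records["value"].to_numpy()
    if np.isnan(X_all).any():
        raise ValueError("genotypes contain missing values; run impute_and_prepare first")
    n = y_all.size

    if partitions is None:
        partitions = make_partitions(
            n, config.n_partitions, config.validation_fraction, config.seed
        )

    out = []
    for name, run in runners.items():
        corr = np.full(len(partitions), np.nan)
        err = np.full(len(partitions), np.nan)
        n_failed = 0
        for part in partitions:
            seed = derive_stream_seed(config.seed, part.partition_index, name)
            try:
                pred = run(
                    X_all[part.train_idx], y_all[part.train_idx], X_all[part.test_idx], seed
                )
                k = part.partition_index - 1
                corr[k] = pearson_correlation(y_all[part.test_idx], pred)
                err[k] = pmse(y_all[part.test_idx], pred)
            except Exception:
                n_failed += 1
                logger.warning(
                    "model %s failed on partition %d", name, part.partition_index,
                    exc_info=True,
                )
        ok = np.isfinite(corr)
        out.append(
            MetricRow(
                model=name,
                trait=trait,
                env=env,
                mean_corr=float(np.mean(corr[ok])) if ok.any() else float("nan"),
                se_corr=float(np.std(corr[ok], ddof=1)) if ok.sum() > 1 else float("nan"),
                mean_pmse=float(np.mean(err[np.isfinite(err)])) if np.isfinite(err).any() else float("nan"),
                n_partitions=len(partitions),
                per_partition_corr=corr,
                per_partition_pmse=err,
                n_failed=n_failed,
            )
        )
    return out


def metric_rows_to_frame(rows: Sequence[MetricRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "model": [r.model for r in rows],
            "trait": [r.trait for r in rows],
            "env": [r.env for r in rows],
            "mean_corr": [r.mean_corr for r in rows],
            "se_corr": [r.se_corr for r in rows],
            "mean_pmse": [r.mean_pmse for r in rows],
            "n_partitions": [r.n_partitions for r in rows],
            "n_failed": [r.n_failed for r in rows],
        }
    )


def pairs_frame(rows: Sequence[MetricRow]) -> pd.DataFrame:
    """Long per-partition correlation table (the paired scatter point cloud)."""
    recs = []
    for r in rows:
        for k, (c, e) in enumerate(zip(r.per_partition_corr, r.per_partition_pmse), 1):
            recs.append(
                {"model": r.model, "trait": r.trait, "env": r.env,
                 "partition": k, "corr": c, "pmse": e}
            )
    return pd.DataFrame(recs)


def _cell(mean: float, se: float) -> str:
    if not np.isfinite(mean):
        return "NA"
    return f"{mean:.2f} ({se:.2f})"


def summarize_benchmark(rows: Sequence[MetricRow]) -> dict:
    """Wide per-environment tables of "mean (SE)" correlation and PMSE strings.

    Returns a dict with ``correlation`` and ``pmse`` DataFrames (index
    (trait, env), columns models), ``best_corr`` / ``best_pmse`` flags and
    the per-partition ``pairs`` point-cloud table.
    """
    if not rows:
        raise ValueError("no metric rows")
    df = metric_rows_to_frame(rows)
    corr_tbl = df.pivot_table(
        index=["trait", "env"], columns="model", values="mean_corr", aggfunc="first"
    )
    se_tbl = df.pivot_table(
        index=["trait", "env"], columns="model", values="se_corr", aggfunc="first"
    )
    pmse_tbl = df.pivot_table(
        index=["trait", "env"], columns="model", values="mean_pmse", aggfunc="first"
    )
    corr_str = corr_tbl.copy().astype(object)
    for idx in corr_tbl.index:
        for col in corr_tbl.columns:
            corr_str.loc[idx, col] = _cell(corr_tbl.loc[idx, col], se_tbl.loc[idx, col])
    pmse_str = pmse_tbl.round(2).astype(object)
    return {
        "correlation": corr_str,
        "pmse": pmse_str,
        "best_corr": corr_tbl.idxmax(axis=1),
        "best_pmse": pmse_tbl.idxmin(axis=1),
        "pairs": pairs_frame(rows),
    }
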