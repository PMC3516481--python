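"""Synthetic genotypes and traits with additive + epistatic architectures.

The generator emulates the statistical shape of an inbred crop line panel typed
with dominant binary markers: roughly 300 lines, a couple of thousand 0/1
markers, traits measured in several environments with broad-sense
heritability anywhere between ~0.1 and ~0.99, and a genetic architecture
mixing additive marker effects with pairwise multiplicative (epistatic)
interactions.  The epistatic component is residualized against the additive
design of the participating markers, so its variance share is exact
in-sample and purely epistatic traits are genuinely invisible to
linear-in-markers models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gpbench.io import GenotypeMatrix

__all__ = ["SimTraitSpec", "SimResult", "simulate_genotypes", "simulate_trait"]


@dataclass
class SimTraitSpec:
    """Genetic architecture of a simulated trait.

    Parameters
    ----------
    n_qtl
        Number of markers with additive effects.
    n_pairs
        Number of marker pairs with multiplicative epistatic effects.
    h2_target
        Target broad-sense heritability per environment, in ``[0, 1]``.
    prop_epistasis
        Share of genetic variance contributed by interaction terms.
    n_env
        Number of environments.
    env_corr
        Genetic correlation of effect sizes across environments.
    effect_dist
        ``"normal"`` (default) or ``"laplace"`` effect-size distribution.
    seed
        RNG seed.
    """

    n_qtl: int
    n_pairs: int = 0
    h2_target: float = 0.5
    prop_epistasis: float = 0.0
    n_env: int = 1
    env_corr: float = 1.0
    effect_dist: str = "normal"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("h2_target", "prop_epistasis", "env_corr"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_qtl < 0 or self.n_pairs < 0:
            raise ValueError("n_qtl and n_pairs must be nonnegative")
        if self.n_env < 1:
            raise ValueError("n_env must be >= 1")
        if self.h2_target == 0.0 and self.prop_epistasis > 0.0:
            raise ValueError("h2_target=0 leaves no genetic variance to apportion")
        if self.effect_dist not in ("normal", "laplace"):
            raise ValueError("effect_dist must be 'normal' or 'laplace'")
        if self.prop_epistasis > 0.0 and self.n_pairs == 0:
            raise ValueError("prop_epistasis > 0 requires n_pairs > 0")
        if self.prop_epistasis < 1.0 and self.h2_target > 0.0 and self.n_qtl == 0:
            raise ValueError("additive variance requested but n_qtl=0")


@dataclass
class SimResult:
    """Realized synthetic trait: truth, genetic values and phenotypes."""

    G: GenotypeMatrix
    additive_effects: np.ndarray          # dense length-p vectors, one per env (p, n_env)
    epistatic_effects: list               # list of (j, k, effects-per-env array)
    g: np.ndarray                         # (n, n_env) true genetic values
    y: np.ndarray                         # (n, n_env) phenotypes, y = g + eps exactly
    eps: np.ndarray                       # (n, n_env) residuals
    realized_h2: np.ndarray               # per-env var(g)/var(y)
    var_additive: np.ndarray = field(default_factory=lambda: np.zeros(0))
    var_epistatic: np.ndarray = field(default_factory=lambda: np.zeros(0))
    sigma_e2: np.ndarray = field(default_factory=lambda: np.zeros(0))


def simulate_genotypes(
    n: int,
    p: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    block_size: int = 1,
    block_r: float = 0.0,
) -> GenotypeMatrix:
    """Simulate an ``n x p`` binary dominant-marker matrix.

    Each marker ``j`` receives a frequency ``q_j ~ Uniform(maf_range)`` and
    entries are Bernoulli(``q_j``).  With ``block_size > 1`` markers in
    consecutive blocks share a per-individual latent Gaussian variable
    (correlation ``block_r`` on the liability scale), a crude stand-in for
    linkage disequilibrium.
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
    if block_size < 1 or not (0.0 <= block_r < 1.0):
        raise ValueError("invalid block-LD parameters")
    rng = np.random.default_rng(seed)
    q = rng.uniform(lo, hi, size=p)
    if block_size == 1 or block_r == 0.0:
        X = (rng.random((n, p)) < q).astype(float)
    else:
        from scipy.stats import norm

        thresh = norm.ppf(q)
        n_blocks = int(np.ceil(p / block_size))
        X = np.empty((n, p))
        for b in range(n_blocks):
            cols = slice(b * block_size, min((b + 1) * block_size, p))
            w = cols.stop - cols.start
            z_shared = rng.standard_normal((n, 1))
            z = np.sqrt(block_r) * z_shared + np.sqrt(1 - block_r) * rng.standard_normal((n, w))
            X[:, cols] = (z < thresh[cols]).astype(float)
    line_ids = [f"L{i+1:04d}" for i in range(n)]
    marker_ids = [f"M{j+1:05d}" for j in range(p)]
    return GenotypeMatrix(line_ids, marker_ids, X, q=X.mean(axis=0))


def _draw_effects(rng: np.random.Generator, size, dist: str) -> np.ndarray:
    if dist == "laplace":
        return rng.laplace(0.0, 1.0 / np.sqrt(2.0), size=size)
    return rng.standard_normal(size)


def _center(v: np.ndarray) -> np.ndarray:
    return v - v.mean()


def simulate_trait(G: GenotypeMatrix, spec: SimTraitSpec) -> SimResult:
    """Simulate multi-environment phenotypes on top of a genotype matrix.

    Construction, per environment:

    1. additive value ``a = X[:, qtl] @ beta`` with effects correlated at
       ``env_corr`` across environments;
    2. raw epistatic value ``sum_l effect_l * x_j * x_k`` over sampled
       marker pairs, residualized in-sample against the intercept, the QTL
       columns and the pair-member columns (fallback: intercept and ``a``),
       making it orthogonal to the additive part;
    3. both parts centered and rescaled so the epistatic variance share is
       exactly ``prop_epistasis`` and ``var(g) = 1``;
    4. ``eps ~ N(0, sigma_e2)`` with ``sigma_e2 = (1 - h2)/h2 * var(g)``
       so the expected heritability is ``h2_target`` (``eps = 0`` exactly
       when ``h2_target = 1``).
    """
    n, p = G.X.shape
    if spec.n_qtl > p:
        raise ValueError("n_qtl exceeds number of markers")
    max_pairs = p * (p - 1) // 2
    if spec.n_pairs > max_pairs:
        raise ValueError("n_pairs exceeds number of distinct marker pairs")
    rng = np.random.default_rng(spec.seed)
    X = G.X
    if np.isnan(X).any():
        raise ValueError("genotypes must be imputed before trait simulation")

    qtl = np.sort(rng.choice(p, size=spec.n_qtl, replace=False)) if spec.n_qtl else np.zeros(0, int)

    # pairs without replacement
    pairs: list[tuple[int, int]] = []
    seen = set()
    while len(pairs) < spec.n_pairs:
        j, k = rng.choice(p, size=2, replace=False)
        key = (min(j, k), max(j, k))
        if key not in seen:
            seen.add(key)
            pairs.append(key)

    rho = spec.env_corr
    n_env = spec.n_env

    def correlated(shape0: int) -> np.ndarray:
        """(shape0, n_env) effects with pairwise correlation rho."""
        common = _draw_effects(rng, shape0, spec.effect_dist)
        out = np.empty((shape0, n_env))
        for e in range(n_env):
            indep = _draw_effects(rng, shape0, spec.effect_dist)
            out[:, e] = np.sqrt(rho) * common + np.sqrt(1.0 - rho) * indep
        return out

    beta_env = correlated(spec.n_qtl) if spec.n_qtl else np.zeros((0, n_env))
    eff_env = correlated(spec.n_pairs) if spec.n_pairs else np.zeros((0, n_env))

    pair_cols = sorted({c for jk in pairs for c in jk})
    prod = np.column_stack([X[:, j] * X[:, k] for j, k in pairs]) if pairs else None

    additive_effects = np.zeros((p, n_env))
    g = np.zeros((n, n_env))
    var_add = np.zeros(n_env)
    var_epi = np.zeros(n_env)
    sigma_e2 = np.zeros(n_env)
    eps = np.zeros((n, n_env))
    y = np.zeros((n, n_env))
    epi_scaled_effects = np.zeros((spec.n_pairs, n_env))

    for e in range(n_env):
        a = X[:, qtl] @ beta_env[:, e] if spec.n_qtl else np.zeros(n)
        a = _center(a)
        if prod is not None:
            epi_raw = prod @ eff_env[:, e]
            D_cols = [np.ones(n)]
            design_idx = sorted(set(qtl.tolist()) | set(pair_cols))
            if 1 + len(design_idx) < n:
                D_cols.extend(X[:, j] for j in design_idx)
            else:
                D_cols.append(a)
            D = np.column_stack(D_cols)
            coef, *_ = np.linalg.lstsq(D, epi_raw, rcond=None)
            epi = epi_raw - D @ coef
        else:
            epi = np.zeros(n)

        va_raw = a.var()
        ve_raw = epi.var()
        if spec.h2_target == 0.0:
            g_e = np.zeros(n)
            s_a = s_e = 0.0
        else:
            pe = spec.prop_epistasis
            if pe > 0.0 and ve_raw <= 0.0:
                raise ValueError("epistatic component degenerate; cannot reach prop_epistasis")
            if pe < 1.0 and va_raw <= 0.0:
                raise ValueError("additive component degenerate")
            s_a = np.sqrt((1.0 - pe) / va_raw) if pe < 1.0 else 0.0
            s_e = np.sqrt(pe / ve_raw) if pe > 0.0 else 0.0
            g_e = s_a * a + s_e * epi
        g[:, e] = g_e
        if spec.n_qtl:
            additive_effects[qtl, e] = s_a * beta_env[:, e]
        if spec.n_pairs:
            epi_scaled_effects[:, e] = s_e * eff_env[:, e]
        var_add[e] = (s_a * a).var()
        var_epi[e] = (s_e * epi).var()

        vg = g_e.var()
        if spec.h2_target >= 1.0:
            sigma_e2[e] = 0.0
        elif spec.h2_target == 0.0:
            sigma_e2[e] = 1.0
        else:
            sigma_e2[e] = vg * (1.0 - spec.h2_target) / spec.h2_target
        eps[:, e] = (
            rng.normal(0.0, np.sqrt(sigma_e2[e]), size=n) if sigma_e2[e] > 0 else np.zeros(n)
        )
        y[:, e] = g[:, e] + eps[:, e]

    vy = y.var(axis=0)
    realized_h2 = np.where(vy > 0, g.var(axis=0) / np.where(vy > 0, vy, 1.0), 0.0)
    epistatic = [(j, k, epi_scaled_effects[l]) for l, (j, k) in enumerate(pairs)]
    return SimResult(
        G=G,
        additive_effects=additive_effects,
        epistatic_effects=epistatic,
        g=g,
        y=y,
        eps=eps,
        realized_h2=realized_h2,
        var_additive=var_add,
        var_epistatic=var_epi,
        sigma_e2=sigma_e2,
    )
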