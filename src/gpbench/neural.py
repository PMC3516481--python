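"""Neural predictors: RBF network (orthogonal least squares) and Bayesian
regularized network (evidence framework).

RBFNN: hidden units are Gaussian radial basis functions centered at selected
training inputs, ``z_k(x) = exp(-h ||x - c_k||^2)`` with a common bandwidth
``h = (0.8326 / spread)^2``.  Centers are chosen by greedy forward selection
with orthogonalization, maximizing the per-step reduction in training MSE,
until the MSE reaches a target (*goal*) or every input is a center.  A
(spread, goal) grid is tuned on an internal split of the training data.

BRNN: a single-hidden-layer tanh network whose parameter vector ``theta``
(connection strengths, biases, output weights, output bias) minimizes the
penalized sum of squares ``F(theta) = beta * sum(e^2) + alpha * sum(theta^2)``
with ``beta = 1/(2 sigma_e2)`` and ``alpha = 1/(2 sigma_theta2)``; the
hyperparameters are re-estimated each outer iteration from the evidence
approximation (effective number of parameters
``gamma = m - 2 alpha trace(H^-1)``), iterating to convergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import pairwise_distances

from gpbench.linear import _align_new, _as_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "RBFNetwork",
    "BRNNetwork",
    "TrainGrid",
    "rbf_bandwidth",
    "ols_select_centers",
    "train_rbfnn",
    "train_brnn",
    "predict_network",
]


@dataclass
class RBFNetwork:
    """A fitted radial basis function network."""

    centers: np.ndarray               # (S, p) selected training inputs
    center_idx: np.ndarray            # indices into the training rows
    h: float                          # common bandwidth (0.8326/spread)^2
    spread: float
    goal: float                       # absolute target training MSE
    weights: np.ndarray               # (S,)
    intercept: float
    mse_path: np.ndarray = field(default_factory=lambda: np.zeros(0))
    train_mse: float = np.nan
    marker_ids: list | None = None

    @property
    def S(self) -> int:
        return int(self.centers.shape[0])


@dataclass
class BRNNetwork:
    """A fitted Bayesian regularized network (posterior-mode weights)."""

    S: int
    theta: np.ndarray                 # packed (w, b, B.ravel(), mu)
    p: int
    alpha: float                      # 1 / (2 sigma_theta2)
    beta_reg: float                   # 1 / (2 sigma_e2)
    sigma_theta2: float
    sigma_e2: float
    gamma: float                      # effective number of parameters
    F_history: np.ndarray
    gamma_history: np.ndarray
    x_mean: np.ndarray
    x_scale: np.ndarray
    group_priors: dict = field(default_factory=dict)
    train_mse: float = np.nan
    marker_ids: list | None = None

    @property
    def m(self) -> int:
        return self.theta.size

    def unpack(self):
        S, p = self.S, self.p
        w = self.theta[:S]
        b = self.theta[S : 2 * S]
        B = self.theta[2 * S : 2 * S + S * p].reshape(S, p)
        mu = self.theta[-1]
        return w, b, B, mu


@dataclass
class TrainGrid:
    """(spread, goal) grid for RBFNN tuning.

    Spreads are the median pairwise Euclidean distance of the training
    inputs times ``spread_multipliers``; goals are ``goal_factors`` times
    ``var(y)`` (set ``relative_goal=False`` for absolute goals).
    """

    spread_multipliers: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    goal_factors: tuple[float, ...] = (0.02, 0.01, 0.005)
    relative_goal: bool = True
    S_max: int | None = None
    tuning_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not self.spread_multipliers or not self.goal_factors:
            raise ValueError("grid must be nonempty")
        if any(s <= 0 for s in self.spread_multipliers):
            raise ValueError("spread multipliers must be positive")
        if any(g < 0 for g in self.goal_factors):
            raise ValueError("goals must be nonnegative")
        if not (0.0 < self.tuning_fraction < 0.5):
            raise ValueError("tuning_fraction must be in (0, 0.5)")


def rbf_bandwidth(spread: float) -> float:
    """Bandwidth of the Gaussian basis, ``h = (0.8326 / spread)^2``."""
    if spread <= 0:
        raise ValueError("spread must be positive")
    return (0.8326 / spread) ** 2


def _rbf_design(X: np.ndarray, centers: np.ndarray, h: float) -> np.ndarray:
    d2 = pairwise_distances(X, centers, metric="euclidean") ** 2
    return np.exp(-h * d2)


def ols_select_centers(
    X_train: np.ndarray,
    y: np.ndarray,
    h: float,
    goal: float = 0.0,
    S_max: int | None = None,
) -> RBFNetwork:
    """Greedy orthogonal-least-squares center selection.

    All training inputs are candidate centers.  The intercept column is in
    the basis from the start; at each step every remaining candidate's RBF
    column is orthogonalized against the current basis and the one with the
    largest error-reduction ratio ``(w'y)^2 / (w'w)`` is added.  Selection
    stops when the training MSE reaches ``goal`` or ``S_max`` centers are
    chosen.  Exact ties go to the lowest candidate index.  Output weights
    are refitted by least squares on the selected (non-orthogonalized)
    columns plus intercept.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if y.size != n:
        raise ValueError("y length mismatch")
    if S_max is None:
        S_max = n
    S_max = min(S_max, n)
    Phi = _rbf_design(X, X, h)
    col_norm0 = np.einsum("ij,ij->j", Phi, Phi)

    # orthogonal basis starts with the intercept
    q0 = np.full(n, 1.0 / np.sqrt(n))
    resid_y = y - q0 * (q0 @ y)
    mse = float(resid_y @ resid_y) / n
    W = Phi - np.outer(q0, q0 @ Phi)     # candidates orthogonalized vs basis
    selected: list[int] = []
    mse_path = [mse]
    available = np.ones(n, dtype=bool)

    while mse > goal and len(selected) < S_max:
        wn = np.einsum("ij,ij->j", W, W)
        valid = available & (wn > 1e-12 * np.maximum(col_norm0, 1e-300))
        if not valid.any():
            if not selected:
                raise ValueError("all candidate columns degenerate")
            logger.info("stopping: remaining candidate columns degenerate")
            break
        wy = W.T @ resid_y
        ratio = np.where(valid, wy**2 / np.where(valid, wn, 1.0), -np.inf)
        j = int(np.argmax(ratio))          # argmax takes the lowest index on ties
        qn = W[:, j] / np.sqrt(wn[j])
        selected.append(j)
        available[j] = False
        resid_y = resid_y - qn * (qn @ resid_y)
        mse = float(resid_y @ resid_y) / n
        mse_path.append(mse)
        W = W - np.outer(qn, qn @ W)
        W[:, j] = 0.0

    idx = np.array(selected, dtype=int)
    A = np.column_stack([np.ones(n), Phi[:, idx]]) if idx.size else np.ones((n, 1))
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    fitted = A @ coef
    train_mse = float(np.mean((y - fitted) ** 2))
    return RBFNetwork(
        centers=X[idx].copy(),
        center_idx=idx,
        h=h,
        spread=0.8326 / np.sqrt(h) if h > 0 else np.inf,
        goal=goal,
        weights=coef[1:] if idx.size else np.zeros(0),
        intercept=float(coef[0]),
        mse_path=np.asarray(mse_path),
        train_mse=train_mse,
    )


def train_rbfnn(
    X_train,
    y,
    grid: TrainGrid | None = None,
    seed: int = 0,
) -> RBFNetwork:
    """Tune (spread, goal) on an internal split, then refit on all training data.

    For each grid cell the OLS selection runs on an 80/20 split of the
    training data (never touching any outer validation fold); the cell with
    the lowest tuning MSE wins and is refitted on the full training data.
    Selection paths are shared across goals of the same spread.
    """
    X, marker_ids = _as_matrix(X_train)
    X = np.ascontiguousarray(X)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if y.size != n:
        raise ValueError("y length mismatch")
    grid = grid or TrainGrid()
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_tune = max(1, int(round(grid.tuning_fraction * n)))
    tune_idx, fit_idx = perm[:n_tune], perm[n_tune:]
    Xf, yf = X[fit_idx], y[fit_idx]
    Xt, yt = X[tune_idx], y[tune_idx]

    d = pairwise_distances(X, metric="euclidean")
    med = float(np.median(d[np.triu_indices(n, k=1)]))
    if med <= 0:
        med = 1.0
    vy = float(y.var())
    goals = sorted(
        {g * vy if grid.relative_goal else g for g in grid.goal_factors}, reverse=True
    )
    S_cap = grid.S_max if grid.S_max is not None else Xf.shape[0]

    best = None
    for mult in grid.spread_multipliers:
        spread = mult * med
        h = rbf_bandwidth(spread)
        # one full path at the tightest goal serves every goal of this spread
        net_full = ols_select_centers(Xf, yf, h, goal=min(goals), S_max=S_cap)
        for goal in goals:
            stop = int(np.searchsorted(-net_full.mse_path, -goal))
            stop = min(stop, net_full.center_idx.size)
            idx = net_full.center_idx[:stop]
            A = np.column_stack([np.ones(Xf.shape[0]), _rbf_design(Xf, Xf[idx], h)]) \
                if idx.size else np.ones((Xf.shape[0], 1))
            coef, *_ = np.linalg.lstsq(A, yf, rcond=None)
            At = np.column_stack([np.ones(Xt.shape[0]), _rbf_design(Xt, Xf[idx], h)]) \
                if idx.size else np.ones((Xt.shape[0], 1))
            tune_mse = float(np.mean((yt - At @ coef) ** 2))
            if best is None or tune_mse < best[0]:
                best = (tune_mse, spread, goal)

    _, spread_win, goal_win = best
    S_final = grid.S_max if grid.S_max is not None else n
    net = ols_select_centers(X, y, rbf_bandwidth(spread_win), goal=goal_win, S_max=S_final)
    net.spread = spread_win
    net.marker_ids = marker_ids
    return net


# ---------------------------------------------------------------------------
# Bayesian regularized neural network
# ---------------------------------------------------------------------------

GROUP_PRIOR_DEFAULTS = {"s_e": 0.05, "df_e": 0.5, "df_u": 0.5}  # s_u = (0.05/p^(1/df_u))^2


def _brnn_forward(theta: np.ndarray, X: np.ndarray, S: int):
    p = X.shape[1]
    w = theta[:S]
    b = theta[S : 2 * S]
    B = theta[2 * S : 2 * S + S * p].reshape(S, p)
    mu = theta[-1]
    U = X @ B.T + b                    # (n, S)
    Z = np.tanh(U)
    f = mu + Z @ w
    return f, Z, w


def _brnn_jacobian(theta: np.ndarray, X: np.ndarray, S: int):
    """Jacobian of the network output wrt theta, one row per observation."""
    n, p = X.shape
    f, Z, w = _brnn_forward(theta, X, S)
    dZ = 1.0 - Z**2                    # tanh'
    J = np.empty((n, theta.size))
    J[:, :S] = Z
    J[:, S : 2 * S] = dZ * w
    # connection strengths: d f / d B_kj = w_k * dZ_k * x_j
    GB = (dZ * w)[:, :, None] * X[:, None, :]      # (n, S, p)
    J[:, 2 * S : 2 * S + S * p] = GB.reshape(n, S * p)
    J[:, -1] = 1.0
    return f, J


def _nguyen_widrow_init(rng: np.random.Generator, S: int, p: int, y: np.ndarray) -> np.ndarray:
    B = rng.uniform(-1.0, 1.0, size=(S, p))
    norms = np.linalg.norm(B, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    scale = 0.7 * S ** (1.0 / p) if p > 0 else 0.7
    B = scale * B / norms
    b = np.linspace(-1.0, 1.0, S) * scale * np.sign(rng.uniform(-1, 1, S))
    w = rng.uniform(-0.5, 0.5, size=S) * float(np.std(y) or 1.0)
    mu = float(np.mean(y))
    return np.concatenate([w, b, B.ravel(), [mu]])


def _minimize_F(theta, X, y, S, alpha, beta, max_inner=60, gtol=1e-8):
    """Levenberg-Marquardt minimization of F = beta*SSE + alpha*SSW."""
    m = theta.size
    lam = 1e-3
    f, J = _brnn_jacobian(theta, X, S)
    e = y - f
    F = beta * float(e @ e) + alpha * float(theta @ theta)
    for _ in range(max_inner):
        g = -2.0 * beta * (J.T @ e) + 2.0 * alpha * theta
        if np.linalg.norm(g, np.inf) < gtol * max(1.0, abs(F)):
            break
        H = 2.0 * beta * (J.T @ J) + 2.0 * alpha * np.eye(m)
        improved = False
        for _ in range(25):
            try:
                step = np.linalg.solve(H + lam * np.eye(m), -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            theta_new = theta + step
            f_new, J_new = _brnn_jacobian(theta_new, X, S)
            e_new = y - f_new
            F_new = beta * float(e_new @ e_new) + alpha * float(theta_new @ theta_new)
            if np.isfinite(F_new) and F_new < F:
                theta, f, J, e, F = theta_new, f_new, J_new, e_new, F_new
                lam = max(lam / 10.0, 1e-12)
                improved = True
                break
            lam *= 10.0
            if lam > 1e12:
                break
        if not improved:
            break
    if not np.isfinite(F):
        raise FloatingPointError("non-finite penalized objective")
    return theta, e, J, F


def train_brnn(
    X_train,
    y,
    S: int = 2,
    max_iter: int = 50,
    tol: float = 1e-6,
    seed: int = 0,
    restarts: int = 5,
    alpha0: float | None = None,
    beta0: float | None = None,
    update_hyper: bool = True,
) -> BRNNetwork:
    """Train a BRNN by the evidence-framework loop.

    Each outer iteration (1) minimizes ``F(theta)`` by Levenberg-Marquardt
    at the current ``(alpha, beta)`` and (2) re-estimates them from the
    evidence approximation: ``gamma = m - 2 alpha trace(H^-1)``,
    ``alpha = gamma / (2 sum theta^2)``, ``beta = (n - gamma)/(2 sum e^2)``.
    The loop stops when the relative change in ``F`` falls below ``tol``,
    or when an outer iteration fails to decrease ``F`` (the hyperparameter
    updates have equilibrated), in which case the previous, lower-``F``
    iterate is kept -- the outer loop accepts only descent steps, like the
    inner Levenberg-Marquardt.  ``(alpha0, beta0)`` default to the
    reciprocal twice-scale of the grouped priors (residual scale 0.05 and
    output-weight scale 0.05, both giving 10.0).
    Inputs are standardized internally; several random restarts are run and
    the solution with the lowest final ``F`` is kept.

    Set ``update_hyper=False`` to freeze ``(alpha, beta)`` at their initial
    values (``alpha0 = 0`` then reduces the fit to unpenalized least
    squares).
    """
    if S < 1:
        raise ValueError("need at least one neuron")
    X_raw, marker_ids = _as_matrix(X_train)
    X_raw = np.ascontiguousarray(X_raw)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X_raw.shape
    if y.size != n:
        raise ValueError("y length mismatch")
    x_mean = X_raw.mean(axis=0)
    x_scale = X_raw.std(axis=0)
    x_scale[x_scale == 0] = 1.0
    X = (X_raw - x_mean) / x_scale
    m = S * (p + 2) + 1
    if beta0 is None:
        beta0 = 1.0 / (2.0 * GROUP_PRIOR_DEFAULTS["s_e"])     # se=0.05 -> beta0=10
    if alpha0 is None:
        alpha0 = 1.0 / (2.0 * 0.05)                        # output-weight group scale
    group_priors = dict(GROUP_PRIOR_DEFAULTS)
    group_priors["s_u"] = (0.05 / p ** (1.0 / group_priors["df_u"])) ** 2

    master = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, restarts)):
        rng = np.random.default_rng(master.integers(2**32))
        theta = _nguyen_widrow_init(rng, S, p, y)
        alpha, beta = float(alpha0), float(beta0)
        F_hist: list[float] = []
        g_hist: list[float] = []
        F_prev = np.inf
        gamma = np.nan
        state_prev = None
        for _outer in range(max_iter):
            theta, e, J, F = _minimize_F(theta, X, y, S, alpha, beta)
            if np.isfinite(F_prev) and F > F_prev * (1.0 + 1e-12) + 1e-12:
                # hyperparameter updates have equilibrated: keep the best iterate
                theta, e, alpha, beta, gamma = state_prev
                break
            F_hist.append(F)
            sse = float(e @ e)
            ssw = float(theta @ theta)
            ev = np.linalg.eigvalsh(J.T @ J)
            ev = np.clip(ev, 0.0, None)
            gamma = float(np.sum(beta * ev / (beta * ev + alpha))) if alpha > 0 else float(m)
            g_hist.append(gamma)
            state_prev = (theta, e, alpha, beta, gamma)
            if update_hyper:
                alpha = gamma / (2.0 * ssw) if ssw > 1e-300 else 0.0
                beta = min((n - gamma) / (2.0 * max(sse, 1e-300)), 1e12)
                if beta <= 0:
                    beta = 1e-6
            if np.isfinite(F_prev) and abs(F_prev - F) <= tol * max(1.0, abs(F_prev)):
                break
            F_prev = F
        sse = float(e @ e)
        cand = BRNNetwork(
            S=S,
            theta=theta,
            p=p,
            alpha=alpha,
            beta_reg=beta,
            sigma_theta2=1.0 / (2.0 * alpha) if alpha > 0 else np.inf,
            sigma_e2=1.0 / (2.0 * beta) if beta > 0 else np.inf,
            gamma=gamma,
            F_history=np.asarray(F_hist),
            gamma_history=np.asarray(g_hist),
            x_mean=x_mean,
            x_scale=x_scale,
            group_priors=group_priors,
            train_mse=sse / n,
            marker_ids=marker_ids,
        )
        if best is None or cand.F_history[-1] < best.F_history[-1]:
            best = cand
    return best


def predict_network(net, X_new) -> np.ndarray:
    """Evaluate a fitted RBF or BRNN network on new inputs."""
    if isinstance(net, RBFNetwork):
        X = _align_new(net.marker_ids, X_new)
        if net.S == 0:
            return np.full(X.shape[0], net.intercept)
        if X.shape[1] != net.centers.shape[1]:
            raise ValueError("marker count mismatch with centers")
        Z = _rbf_design(X, net.centers, net.h)
        return net.intercept + Z @ net.weights
    if isinstance(net, BRNNetwork):
        X = _align_new(net.marker_ids, X_new)
        if X.shape[1] != net.p:
            raise ValueError("marker count mismatch with network inputs")
        Xs = (X - net.x_mean) / net.x_scale
        f, _, _ = _brnn_forward(net.theta, Xs, net.S)
        return f
    raise TypeError(f"unsupported network type {type(net)!r}")
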