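import numpy as np
import pytest

from gpbench import (
    BRNNetwork,
    RBFNetwork,
    TrainGrid,
    ols_select_centers,
    predict_network,
    rbf_bandwidth,
    train_brnn,
    train_rbfnn,
)


def _rbf_col(X, c, h):
    return np.exp(-h * np.sum((X - c) ** 2, axis=1))


class TestBandwidth:
    def test_forced_unit_value(self):
        assert rbf_bandwidth(0.8326) == pytest.approx(1.0, abs=1e-12)

    def test_hand_value(self):
        assert rbf_bandwidth(1.6652) == pytest.approx(0.25, abs=1e-12)

    def test_monotone_decreasing(self):
        spreads = np.linspace(0.1, 50, 40)
        hs = [rbf_bandwidth(s) for s in spreads]
        assert np.all(np.diff(hs) < 0)

    def test_positive_spread_required(self):
        with pytest.raises(ValueError):
            rbf_bandwidth(0.0)


class TestOLSCenterSelection:
    def test_first_pick_matches_exhaustive_search(self, rng):
        X = rng.standard_normal((20, 3))
        y = np.sin(X[:, 0]) + 0.5 * X[:, 1] + rng.standard_normal(20) * 0.1
        h = 0.8
        net = ols_select_centers(X, y, h=h, goal=0.0, S_max=1)
        # brute force: best single center by residual SSE after intercept+column LS
        best_sse, best_j = np.inf, -1
        for j in range(20):
            A = np.column_stack([np.ones(20), _rbf_col(X, X[j], h)])
            r = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
            sse = r @ r
            if sse < best_sse - 1e-12:
                best_sse, best_j = sse, j
        assert net.center_idx[0] == best_j

    def test_constant_y_zero_centers(self):
        X = np.arange(12.0).reshape(6, 2)
        net = ols_select_centers(X, np.full(6, 3.0), h=1.0, goal=1e-12)
        assert net.S == 0
        assert net.train_mse < 1e-20
        assert net.intercept == pytest.approx(3.0)

    def test_interpolation_at_goal_zero(self, rng):
        X = rng.standard_normal((15, 2))
        y = rng.standard_normal(15)
        net = ols_select_centers(X, y, h=1.0, goal=0.0, S_max=15)
        assert net.train_mse < 1e-8

    def test_mse_path_non_increasing(self, rng):
        X = rng.standard_normal((25, 3))
        y = rng.standard_normal(25)
        net = ols_select_centers(X, y, h=0.5, goal=0.0, S_max=25)
        assert np.all(np.diff(net.mse_path) <= 1e-12)

    def test_greedy_matches_exhaustive_for_two_centers(self, rng):
        # greedy achieves the same MSE as exhaustive search at S<=2 on tiny toys
        X = rng.standard_normal((12, 2))
        y = np.cos(X[:, 0]) + rng.standard_normal(12) * 0.05
        h = 1.0
        net = ols_select_centers(X, y, h=h, goal=0.0, S_max=2)
        best = np.inf
        for j in range(12):
            for k in range(12):
                if j == k:
                    continue
                A = np.column_stack(
                    [np.ones(12), _rbf_col(X, X[j], h), _rbf_col(X, X[k], h)]
                )
                r = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
                best = min(best, float(r @ r) / 12)
        # greedy is near-optimal on these toys (allow small slack)
        assert net.train_mse <= best * 1.5 + 1e-10


class TestTrainRBFNN:
    def test_singleton_grid_equals_direct_fit(self, rng):
        X = rng.standard_normal((30, 2))
        y = np.sin(X[:, 0]) + rng.standard_normal(30) * 0.1
        grid = TrainGrid(spread_multipliers=(1.0,), goal_factors=(0.01,))
        net = train_rbfnn(X, y, grid=grid, seed=0)
        direct = ols_select_centers(X, y, h=net.h, goal=net.goal, S_max=30)
        np.testing.assert_array_equal(net.center_idx, direct.center_idx)
        np.testing.assert_allclose(net.weights, direct.weights)

    def test_recovers_generating_spread(self):
        hits = 0
        spread_true = 1.0
        h_true = rbf_bandwidth(spread_true)
        for s in range(10):
            rng = np.random.default_rng(s)
            X = rng.uniform(-2, 2, size=(80, 2))
            centers = X[:3]
            y = sum(
                w * _rbf_col(X, c, h_true)
                for w, c in zip((2.0, -1.5, 1.0), centers)
            ) + rng.standard_normal(80) * 0.05
            med = np.median(
                np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))[
                    np.triu_indices(80, 1)
                ]
            )
            grid = TrainGrid(
                spread_multipliers=(0.25 / med, 1.0 / med, 4.0 / med),
                goal_factors=(0.01,),
            )
            net = train_rbfnn(X, y, grid=grid, seed=s)
            if abs(net.spread - spread_true) < 1e-9:
                hits += 1
        assert hits >= 8

    def test_determinism(self, rng):
        X = rng.standard_normal((40, 3))
        y = rng.standard_normal(40)
        a = train_rbfnn(X, y, seed=3)
        b = train_rbfnn(X, y, seed=3)
        assert a.spread == b.spread and a.goal == b.goal
        np.testing.assert_array_equal(a.center_idx, b.center_idx)
        np.testing.assert_array_equal(a.weights, b.weights)


class TestTrainBRNN:
    @staticmethod
    def _two_neuron_data(seed, n=60, p=3):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, p))
        B = rng.standard_normal((2, p))
        y = 0.7 + np.tanh(X @ B.T + np.array([0.3, -0.5])) @ np.array([1.5, -2.0])
        return X, y

    def test_alpha_zero_recovers_least_squares(self):
        # tiny weights => network is effectively linear; alpha=0 is plain LS
        rng = np.random.default_rng(1)
        X = rng.standard_normal((50, 2))
        y = 0.05 * X[:, 0] - 0.03 * X[:, 1] + 0.2
        net = train_brnn(X, y, S=1, seed=0, restarts=3, alpha0=0.0, beta0=1.0,
                         update_hyper=False)
        resid = y - predict_network(net, X)
        assert float(resid @ resid) / 50 < 1e-6
        # F equals beta * RSS at the optimum when alpha = 0
        assert net.F_history[-1] == pytest.approx(1.0 * float(resid @ resid), rel=1e-6)

    def test_gamma_within_bounds(self):
        for s in range(5):
            X, y = self._two_neuron_data(s)
            y = y + np.random.default_rng(s).standard_normal(60) * 0.1
            net = train_brnn(X, y, S=2, seed=s, restarts=1, max_iter=30)
            assert np.all(net.gamma_history >= -1e-9)
            assert np.all(net.gamma_history <= net.m + 1e-9)

    def test_noiseless_recovery_and_monotone_objective(self):
        ok_mse = 0
        ok_mono = 0
        for s in range(10):
            X, y = self._two_neuron_data(100 + s)
            net = train_brnn(X, y, S=2, seed=s, restarts=1, max_iter=50)
            if net.train_mse < 1e-4:
                ok_mse += 1
            diffs = np.diff(net.F_history)
            if np.all(diffs <= 1e-8 * np.maximum(1.0, np.abs(net.F_history[:-1]))):
                ok_mono += 1
        assert ok_mse >= 8
        assert ok_mono >= 8

    def test_shrinkage_reduces_weight_norm(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((40, 3))
        y = np.tanh(X @ rng.standard_normal((2, 3)).T) @ np.array([1.0, -1.0])
        y = y + rng.standard_normal(40) * 0.3
        free = train_brnn(X, y, S=2, seed=1, restarts=2, alpha0=0.0, beta0=1.0,
                          update_hyper=False)
        pen = train_brnn(X, y, S=2, seed=1, restarts=2, alpha0=0.5, beta0=1.0,
                         update_hyper=False)
        assert np.linalg.norm(pen.theta) < np.linalg.norm(free.theta)

    def test_hyperparameters_map_to_variances(self):
        X, y = self._two_neuron_data(9)
        y = y + np.random.default_rng(9).standard_normal(60) * 0.2
        net = train_brnn(X, y, S=2, seed=2, restarts=1)
        assert net.sigma_e2 == pytest.approx(1.0 / (2.0 * net.beta_reg))
        assert net.sigma_theta2 == pytest.approx(1.0 / (2.0 * net.alpha))
        assert net.group_priors["s_e"] == 0.05
        assert net.group_priors["df_e"] == 0.5
        assert net.group_priors["s_u"] == pytest.approx((0.05 / 3.0 ** 2) ** 2)


class TestPredictNetwork:
    def test_rbf_zero_weights_constant(self):
        net = RBFNetwork(
            centers=np.zeros((2, 3)), center_idx=np.array([0, 1]), h=1.0,
            spread=0.8326, goal=0.0, weights=np.zeros(2), intercept=1.5,
        )
        np.testing.assert_allclose(predict_network(net, np.ones((4, 3))), 1.5)

    def test_rbf_at_center(self):
        centers = np.array([[0.0, 0.0], [100.0, 100.0]])
        net = RBFNetwork(
            centers=centers, center_idx=np.array([0, 1]), h=1.0,
            spread=0.8326, goal=0.0, weights=np.array([2.0, 5.0]), intercept=1.0,
        )
        pred = predict_network(net, np.array([[0.0, 0.0]]))
        assert pred[0] == pytest.approx(3.0, abs=1e-10)

    def test_brnn_hand_computed(self):
        # 1 neuron: b=0, beta=(1,0), w=2, mu=0, x=(0.5,9) -> 2*tanh(0.5)
        theta = np.array([2.0, 0.0, 1.0, 0.0, 0.0])
        net = BRNNetwork(
            S=1, theta=theta, p=2, alpha=0.0, beta_reg=1.0,
            sigma_theta2=np.inf, sigma_e2=0.5, gamma=0.0,
            F_history=np.array([0.0]), gamma_history=np.array([0.0]),
            x_mean=np.zeros(2), x_scale=np.ones(2),
        )
        pred = predict_network(net, np.array([[0.5, 9.0]]))
        g = (np.e - 1.0) / (np.e + 1.0)  # tanh(0.5)
        assert pred[0] == pytest.approx(2.0 * g, abs=1e-9)
        assert pred[0] == pytest.approx(0.924234, abs=1e-5)

    def test_unsupported_type(self):
        with pytest.raises(TypeError):
            predict_network(object(), np.zeros((1, 2)))
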