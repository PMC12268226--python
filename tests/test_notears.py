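import itertools

import networkx as nx
import numpy as np
import pytest
import scipy.optimize

import cohortdag as cd
from cohortdag.notears import FitSettings, WeightMatrix


class TestSquaredLoss:
    def test_zero_weights_give_frobenius_norm(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 4))
        loss, _ = cd.squared_loss(X, np.zeros((4, 4)))
        assert loss == pytest.approx(np.sum(X**2) / (2 * 50))

    def test_noiseless_chain_leaves_only_root_residual(self):
        # x1 -> x2 (2.0) -> x3 (-1.0) with no child noise: at the true W the
        # residual X - XW is zero for both children, so the loss reduces to
        # the root column's own variance term.
        rng = np.random.default_rng(1)
        x1 = rng.normal(size=200)
        W = np.array([[0, 2.0, 0], [0, 0, -1.0], [0, 0, 0]])
        X = np.column_stack([x1, 2 * x1, -2 * x1])
        loss, _ = cd.squared_loss(X, W)
        assert loss == pytest.approx(np.sum(x1**2) / (2 * 200), abs=1e-12)
        assert np.abs((X - X @ W)[:, 1:]).max() == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        X = np.array([[1.0, 2.0], [3.0, 4.0]])
        W = np.array([[0.0, 1.0], [0.0, 0.0]])
        # R = X - XW = [[1,1],[3,1]]; ||R||^2 = 12; loss = 12/(2*2) = 3
        loss, grad = cd.squared_loss(X, W)
        assert loss == pytest.approx(3.0)
        np.testing.assert_allclose(grad, [[-5.0, -2.0], [-7.0, -3.0]])

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            cd.squared_loss(np.zeros((5, 3)), np.zeros((2, 2)))


class TestAcyclicity:
    def test_zero_matrix(self):
        for d in (1, 3, 7):
            h, _ = cd.acyclicity(np.zeros((d, d)))
            assert h == pytest.approx(0.0, abs=1e-12)

    def test_upper_triangular_is_acyclic(self):
        rng = np.random.default_rng(2)
        W = np.triu(rng.normal(size=(5, 5)), k=1)
        h, _ = cd.acyclicity(W)
        assert h == pytest.approx(0.0, abs=1e-9)

    def test_unit_two_cycle_closed_form(self):
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        h, _ = cd.acyclicity(W)
        assert h == pytest.approx(2 * np.cosh(1.0) - 2, abs=1e-10)

    def test_agrees_with_cycle_detection_oracle(self):
        """h < 1e-9 iff the support is cycle-free, on 1000 random matrices."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            d = int(rng.integers(2, 7))
            support = rng.random((d, d)) < 0.3
            np.fill_diagonal(support, False)
            W = support * rng.uniform(0.5, 1.5, (d, d)) * rng.choice([-1, 1], (d, d))
            h, _ = cd.acyclicity(W)
            has_cycle = not nx.is_directed_acyclic_graph(
                nx.from_numpy_array(W != 0, create_using=nx.DiGraph)
            )
            assert (h >= 1e-9) == has_cycle, f"h={h}, cyclic={has_cycle}\n{W}"


class TestGradients:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_loss_gradient_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(30, 4))
        W = rng.normal(scale=0.4, size=(4, 4))
        _, grad = cd.squared_loss(X, W)
        num = _central_diff(lambda M: cd.squared_loss(X, M)[0], W)
        np.testing.assert_allclose(grad, num, rtol=1e-5, atol=1e-7)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_acyclicity_gradient_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        W = rng.normal(scale=0.5, size=(5, 5))
        _, grad = cd.acyclicity(W)
        num = _central_diff(lambda M: cd.acyclicity(M)[0], W)
        np.testing.assert_allclose(grad, num, rtol=1e-5, atol=1e-7)


def _central_diff(f, W, eps=1e-6):
    G = np.zeros_like(W)
    for i in range(W.shape[0]):
        for j in range(W.shape[1]):
            Wp, Wm = W.copy(), W.copy()
            Wp[i, j] += eps
            Wm[i, j] -= eps
            G[i, j] = (f(Wp) - f(Wm)) / (2 * eps)
    return G


class TestFit:
    def test_single_node_returns_empty_matrix(self):
        w = cd.notears_fit(np.random.default_rng(0).normal(size=(20, 1)))
        assert w.W.shape == (1, 1) and w.h == 0.0

    def test_two_node_recovery_matches_ols_slope(self):
        rng = np.random.default_rng(10)
        x1 = rng.normal(size=500)
        x2 = 2.0 * x1 + rng.normal(scale=0.5, size=500)
        X = np.column_stack([x1, x2])
        w = cd.notears_fit(X, FitSettings())
        x1c, x2c = x1 - x1.mean(), x2 - x2.mean()
        ols = float(x1c @ x2c / (x1c @ x1c))
        assert abs(w.W[0, 1]) == pytest.approx(abs(ols), abs=0.2)
        assert abs(w.W[0, 1] - 2.0) < 0.2
        assert abs(w.W[1, 0]) < 0.1

    def test_three_node_chain_support_beats_all_dags(self, chain3_data):
        """Thresholded support equals {A->B, B->C}; exhaustive scoring over
        all 25 DAGs on 3 nodes confirms it is the best two-edge structure,
        and the fit reaches the global least-squares optimum over DAGs."""
        X = chain3_data
        w = cd.notears_fit(X, FitSettings())
        support = set(zip(*np.nonzero(np.abs(w.W) > 0.3)))
        assert support == {(0, 1), (1, 2)}
        assert w.loss <= cd.squared_loss(X - X.mean(0), np.zeros((3, 3)))[0]

        scored = _score_all_dags(X)
        best_loss = min(loss for _, loss in scored)
        best_two_edge = min((s for s in scored if len(s[0]) <= 2), key=lambda s: s[1])
        assert best_two_edge[0] == {(0, 1), (1, 2)}
        # unpenalized least squares cannot distinguish supergraphs of the
        # truth, but the fit must reach that optimal value
        assert w.loss <= best_loss + 1e-3

    def test_returned_point_dominates_zero(self, chain3_data):
        w = cd.notears_fit(chain3_data)
        zero_loss = cd.squared_loss(chain3_data - chain3_data.mean(0), np.zeros((3, 3)))[0]
        assert w.loss <= zero_loss + 1e-9

    def test_permutation_equivariance(self, chain3_data):
        perm = [2, 0, 1]
        w1 = cd.notears_fit(chain3_data, FitSettings())
        w2 = cd.notears_fit(chain3_data[:, perm], FitSettings())
        P = np.eye(3)[perm]
        np.testing.assert_allclose(P @ w1.W @ P.T, w2.W, atol=5e-3)

    def test_matches_scipy_lbfgsb_reference(self, chain3_data):
        """The jitted solver and scipy's L-BFGS-B on the identical augmented
        Lagrangian agree on the fitted weights."""
        X = chain3_data
        w_fast = cd.notears_fit(X, FitSettings())
        w_ref = _scipy_reference_fit(X)
        np.testing.assert_allclose(w_fast.W, w_ref, atol=5e-3)

    def test_nonfinite_input_rejected(self):
        X = np.ones((10, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            cd.notears_fit(X)

    def test_l1_penalty_shrinks_weights(self, chain3_data):
        w0 = cd.notears_fit(chain3_data, FitSettings(lambda1=0.0))
        w1 = cd.notears_fit(chain3_data, FitSettings(lambda1=0.5))
        assert np.abs(w1.W).sum() < np.abs(w0.W).sum()
        assert w1.converged


def _score_all_dags(X):
    """Brute-force oracle: least-squares loss of every DAG on X's nodes,
    with OLS weights on each parent set."""
    n, d = X.shape
    Xc = X - X.mean(0)
    scored = []
    edges = [(i, j) for i in range(d) for j in range(d) if i != j]
    for r in range(len(edges) + 1):
        for combo in itertools.combinations(edges, r):
            g = nx.DiGraph(combo)
            g.add_nodes_from(range(d))
            if not nx.is_directed_acyclic_graph(g):
                continue
            W = np.zeros((d, d))
            for j in range(d):
                parents = [i for i, jj in combo if jj == j]
                if parents:
                    A = Xc[:, parents]
                    W[parents, j] = np.linalg.lstsq(A, Xc[:, j], rcond=None)[0]
            loss, _ = cd.squared_loss(Xc, W)
            scored.append((set(combo), loss))
    return scored


def _scipy_reference_fit(X, h_tol=1e-8, rho_max=1e16):
    n, d = X.shape
    Xc = X - X.mean(0)
    S = Xc.T @ Xc

    def obj(w, rho, alpha):
        W = w.reshape(d, d)
        M = np.eye(d) - W
        SM = S @ M
        loss = 0.5 / n * float(np.sum(M * SM))
        h, gh = cd.acyclicity(W)
        f = loss + alpha * h + 0.5 * rho * h * h
        g = -SM / n + (alpha + rho * h) * gh
        np.fill_diagonal(g, 0.0)
        return f, g.ravel()

    w, rho, alpha, h = np.zeros(d * d), 1.0, 0.0, np.inf
    for _ in range(100):
        while rho < rho_max:
            res = scipy.optimize.minimize(obj, w, args=(rho, alpha), jac=True, method="L-BFGS-B")
            h_new = cd.acyclicity(res.x.reshape(d, d))[0]
            if h_new > 0.25 * h:
                rho *= 10
            else:
                break
        w, h = res.x, h_new
        alpha += rho * h
        if h <= h_tol or rho >= rho_max:
            break
    return w.reshape(d, d)


class TestWeightMatrix:
    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            WeightMatrix(np.eye(2), ["a", "b"])

    def test_csv_round_trip(self, tmp_path):
        w = WeightMatrix(np.array([[0.0, 1.5], [0.0, 0.0]]), ["a", "b"])
        w.to_csv(tmp_path / "w.csv")
        back = WeightMatrix.from_csv(tmp_path / "w.csv")
        np.testing.assert_allclose(back.W, w.W)
        assert back.nodes == ["a", "b"]
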