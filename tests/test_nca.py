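"""NCA: soft assignment probabilities, objective, gradient, optimization."""

import numpy as np
import pytest

from resuskit import nca


def finite_difference_gradient(A, X, y, h=1e-6):
    fd = np.zeros_like(A)
    for i in range(A.shape[0]):
        for j in range(A.shape[1]):
            up, down = A.copy(), A.copy()
            up[i, j] += h
            down[i, j] -= h
            fd[i, j] = (nca.objective(up, X, y) - nca.objective(down, X, y)) / (2 * h)
    return fd


class TestSoftNeighborProbabilities:
    def test_two_points_single_neighbor(self):
        P = nca.soft_neighbor_probabilities(np.array([[0.0, 1.0]]))
        assert np.allclose(P, [[0, 1], [1, 0]])

    def test_equilateral_triangle_uniform(self):
        W = np.array([[0.0, 1.0, 0.5], [0.0, 0.0, np.sqrt(3) / 2]])
        P = nca.soft_neighbor_probabilities(W)
        off = P[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.5)

    def test_rows_sum_to_one_diagonal_zero(self):
        rng = np.random.default_rng(0)
        W = rng.normal(size=(3, 6))
        P = nca.soft_neighbor_probabilities(W)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(np.diag(P) == 0)

    def test_huge_distances_do_not_underflow_rows(self):
        W = np.array([[0.0, 1e4, 2.5e4]])
        P = nca.soft_neighbor_probabilities(W)
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            nca.soft_neighbor_probabilities(np.array([[1.0]]))


class TestObjective:
    def test_two_points_same_class(self):
        X = np.array([[0.0, 1.0]])
        assert nca.objective(np.eye(1), X, np.array([0, 0])) == pytest.approx(2.0)

    def test_two_points_different_class(self):
        X = np.array([[0.0, 1.0]])
        assert nca.objective(np.eye(1), X, np.array([0, 1])) == pytest.approx(0.0)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(3, 5))
        y = np.array([0, 1, 0, 1, 0])
        A = rng.normal(size=(2, 3))
        W = A @ X
        expected = 0.0
        for j in range(5):
            denom = sum(
                np.exp(-np.sum((W[:, j] - W[:, l]) ** 2)) for l in range(5) if l != j
            )
            for k in range(5):
                if k != j and y[k] == y[j]:
                    expected += np.exp(-np.sum((W[:, j] - W[:, k]) ** 2)) / denom
        assert nca.objective(A, X, y) == pytest.approx(expected, rel=1e-12)

    def test_bounded_by_point_count(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(4, 9))
        y = rng.integers(0, 3, 9)
        f = nca.objective(rng.normal(size=(2, 4)), X, y)
        assert 0.0 <= f <= 9.0

    def test_label_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            nca.objective(np.eye(2), np.zeros((2, 3)), np.array([0, 1]))


class TestGradient:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        D, M = 4, 6
        X = rng.normal(size=(D, M))
        y = rng.integers(0, 2, M)
        A = rng.normal(size=(2, D))
        g = nca.gradient(A, X, y)
        fd = finite_difference_gradient(A, X, y)
        assert np.max(np.abs(g - fd)) <= 1e-5 * max(np.max(np.abs(fd)), 1.0)

    def test_collapsed_embedding_gradient(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(3, 5))
        y = np.array([0, 0, 1, 1, 1])
        A = np.zeros((2, 3))  # all points collapse: P is uniform
        g = nca.gradient(A, X, y)
        fd = finite_difference_gradient(A, X, y)
        assert np.allclose(g, fd, atol=1e-6)

    def test_single_class_gradient_small(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(3, 6))
        y = np.zeros(6, dtype=int)
        A = rng.normal(size=(2, 3)) * 0.1
        g = nca.gradient(A, X, y)
        fd = finite_difference_gradient(A, X, y)
        assert np.allclose(g, fd, atol=1e-6)
        # every neighbor is in-class: f is near its ceiling, gradient tiny
        assert np.max(np.abs(g)) < 1.0


class TestInvariances:
    def test_rotation_invariance_of_objective(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(5, 8))
        y = rng.integers(0, 2, 8)
        A = rng.normal(size=(2, 5))
        theta = 0.7
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        assert nca.objective(R @ A, X, y) == pytest.approx(
            nca.objective(A, X, y), rel=1e-12
        )

    def test_translation_invariance_of_objective(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(5, 8))
        y = rng.integers(0, 2, 8)
        A = rng.normal(size=(2, 5))
        # shifting every input point equally leaves pairwise distances alone
        X2 = rng.normal(size=(5, 8))
        shift = rng.normal(size=(5, 1))
        assert nca.objective(A, X2 + shift, y) == pytest.approx(
            nca.objective(A, X2, y), rel=1e-9
        )


class TestFit:
    def test_separated_blobs_reach_near_ceiling(self):
        rng = np.random.default_rng(0)
        X = np.concatenate(
            [rng.normal(0, 1, (10, 20)), rng.normal(10, 1, (10, 20))], axis=1
        )
        y = np.array([0] * 20 + [1] * 20)
        model = nca.fit(X, y, d_out=2, seed=0)
        assert model.objective_trace[-1] >= 0.95 * 40

    def test_trace_non_decreasing(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(6, 30)) + np.repeat([0, 3], 15)[None, :]
        y = np.repeat([0, 1], 15)
        model = nca.fit(X, y, d_out=2, seed=1, max_iter=100)
        trace = np.array(model.objective_trace)
        assert np.all(np.diff(trace) >= -1e-10)

    def test_single_class_converges_quickly(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(4, 10))
        y = np.zeros(10, dtype=int)
        model = nca.fit(X, y, d_out=4, seed=0)
        assert model.converged
        assert model.objective_trace[-1] == pytest.approx(10.0, abs=0.5)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(5, 16))
        y = rng.integers(0, 2, 16)
        m1 = nca.fit(X, y, seed=42, max_iter=50)
        m2 = nca.fit(X, y, seed=42, max_iter=50)
        assert np.array_equal(m1.A, m2.A)

    def test_transform_centers_then_maps(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(3, 12)) + 100.0
        y = rng.integers(0, 2, 12)
        model = nca.fit(X, y, max_iter=5, seed=0)
        W = model.transform(X)
        assert np.allclose(
            W, model.A @ (X - X.mean(axis=1, keepdims=True)), atol=1e-9
        )

    def test_nonfinite_input_rejected(self):
        X = np.full((3, 4), np.nan)
        with pytest.raises(ValueError):
            nca.fit(X, np.zeros(4, dtype=int))

    def test_matches_sklearn_on_separable_data(self):
        # independent cross-check: scikit-learn's NCA maximizes the same
        # objective; on well-separated blobs both routes should approach the
        # ceiling f ~ M when scored by this module's objective function
        from sklearn.neighbors import NeighborhoodComponentsAnalysis

        rng = np.random.default_rng(21)
        X = np.concatenate(
            [rng.normal(0, 1, (6, 15)), rng.normal(8, 1, (6, 15))], axis=1
        )
        y = np.array([0] * 15 + [1] * 15)
        ours = nca.fit(X, y, d_out=2, seed=0)
        Xc = X - X.mean(axis=1, keepdims=True)
        skl = NeighborhoodComponentsAnalysis(
            n_components=2, random_state=0, max_iter=200
        ).fit(Xc.T, y)
        f_ours = nca.objective(ours.A, Xc, y)
        f_skl = nca.objective(skl.components_, Xc, y)
        assert f_ours >= 0.9 * 30
        assert f_skl >= 0.9 * 30
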