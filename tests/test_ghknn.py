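import numpy as np
import pytest
from scipy.optimize import minimize

from ghknn.exceptions import ConfigurationError, ContractError
from ghknn.ghknn import (
    GHKNNClassifier,
    GHKNNParams,
    _kernel_matrix,
    build_graph_laplacian,
    build_hyperplane,
    class_distance,
    hknn_distance,
    hyperplane_distance,
    predict,
    rbf_kernel,
    select_neighbors,
)


class TestParams:
    def test_defaults_match_tuned_operating_point(self):
        p = GHKNNParams()
        assert p.lam == 0.01
        assert p.gamma == 2.0 ** -15 == 3.0517578125e-05
        assert p.mu == 0.1
        assert p.kernel == "rbf"

    @pytest.mark.parametrize(
        "kwargs", [{"lam": 0}, {"lam": -1}, {"gamma": 0}, {"mu": -0.1},
                   {"k": 0}, {"kernel": "poly"}]
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ConfigurationError):
            GHKNNParams(**kwargs)


class TestRbfKernel:
    def test_zero_distance(self):
        x = np.array([1.0, 2.0])
        assert rbf_kernel(x, x, 0.5) == 1.0

    def test_gamma_to_zero_limit(self, rng):
        a, b = rng.normal(size=4), rng.normal(size=4)
        assert rbf_kernel(a, b, 1e-12) == pytest.approx(1.0, abs=1e-9)

    def test_closed_form(self):
        v = rbf_kernel(np.zeros(2), np.ones(2), 0.5)
        assert v == pytest.approx(np.exp(-1.0))

    def test_dimension_mismatch(self):
        with pytest.raises(ContractError):
            rbf_kernel(np.zeros(2), np.zeros(3), 1.0)

    def test_kernel_matrix_symmetric_psd(self, rng):
        A = rng.normal(size=(6, 3))
        K = _kernel_matrix(A, A, GHKNNParams(gamma=0.3))
        np.testing.assert_allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() > -1e-10


class TestSelectNeighbors:
    def test_k_exceeds_class_size(self, rng):
        rows = rng.normal(size=(3, 2))
        assert len(select_neighbors(np.zeros(2), rows, 10)) == 3

    def test_exact_match_first(self, rng):
        rows = rng.normal(size=(5, 2))
        idx = select_neighbors(rows[3], rows, 1)
        assert idx[0] == 3

    def test_against_brute_force_sort(self, rng):
        x = np.array([2.5])
        rows = np.array([[0.0], [1.0], [2.0], [3.0], [4.0]])
        idx = select_neighbors(x, rows, 2)
        brute = sorted(range(5), key=lambda i: (abs(rows[i, 0] - 2.5), i))[:2]
        assert sorted(idx.tolist()) == sorted(brute)

    def test_tie_goes_to_lower_index(self):
        rows = np.array([[1.0], [-1.0], [1.0]])
        idx = select_neighbors(np.zeros(1), rows, 2)
        assert idx.tolist() == [0, 1]

    def test_empty_class(self):
        with pytest.raises(ContractError):
            select_neighbors(np.zeros(2), np.zeros((0, 2)), 3)


class TestGraphLaplacian:
    def test_single_node(self):
        np.testing.assert_array_equal(build_graph_laplacian(np.zeros((1, 3)), 0.5), [[0.0]])

    def test_two_nodes(self):
        V = np.array([[0.0], [1.0]])
        w = np.exp(-0.5)
        np.testing.assert_allclose(
            build_graph_laplacian(V, 0.5), [[w, -w], [-w, w]]
        )

    def test_symmetric_psd_zero_rowsums(self, rng):
        L = build_graph_laplacian(rng.normal(size=(5, 3)), 0.7)
        np.testing.assert_allclose(L, L.T)
        np.testing.assert_allclose(L.sum(axis=1), 0.0, atol=1e-10)
        assert np.linalg.eigvalsh(L).min() > -1e-10

    def test_quadratic_form_equals_double_sum(self, rng):
        V = rng.normal(size=(4, 2))
        gamma = 0.4
        L = build_graph_laplacian(V, gamma)
        alpha = rng.normal(size=4)
        W = np.exp(-gamma * np.sum((V[:, None] - V[None]) ** 2, axis=2))
        np.fill_diagonal(W, 0.0)
        double_sum = sum(
            W[p, q] * (alpha[p] - alpha[q]) ** 2
            for p in range(4) for q in range(4)
        )
        assert alpha @ L @ alpha == pytest.approx(0.5 * double_sum)


class TestSolveAlpha:
    def test_single_neighbor_scalar_case(self):
        p = GHKNNParams()  # lam = 0.01
        x = np.array([3.0, -1.0])
        hp = build_hyperplane(x, x[None, :], p)
        assert hp.alpha[0] == pytest.approx(1 / 1.01)

    def test_residual_bound(self, rng):
        for _ in range(10):
            rows = rng.normal(size=(8, 5))
            x = rng.normal(size=5)
            p = GHKNNParams(gamma=0.2, mu=0.5, k=6)
            hp = build_hyperplane(x, rows, p)
            K = _kernel_matrix(hp.centered, hp.centered, p)
            b = _kernel_matrix(hp.centered, (x - hp.centroid)[None], p).ravel()
            A = K + p.lam * np.eye(len(K)) + p.mu * hp.laplacian
            assert np.max(np.abs(A @ hp.alpha - b)) <= 1e-8

    def test_matches_numerical_minimizer(self, rng):
        for _ in range(10):
            d = int(rng.integers(2, 10))
            kp = int(rng.integers(1, 7))
            rows = rng.normal(size=(kp, d))
            x = rng.normal(size=d)
            p = GHKNNParams(
                lam=float(10 ** rng.uniform(-3, 0)),
                gamma=float(10 ** rng.uniform(-3, 0)),
                mu=float(rng.uniform(0, 1)),
                k=kp,
            )
            hp = build_hyperplane(x, rows, p)
            K = _kernel_matrix(hp.centered, hp.centered, p)
            b = _kernel_matrix(hp.centered, (x - hp.centroid)[None], p).ravel()
            L = hp.laplacian

            def objective(a):
                return p.lam * a @ a + p.mu * a @ L @ a + 1.0 - 2 * b @ a + a @ K @ a

            res = minimize(objective, np.zeros(kp), method="BFGS",
                           options={"gtol": 1e-12})
            np.testing.assert_allclose(res.x, hp.alpha, atol=1e-4)

    def test_nonfinite_rejected(self):
        p = GHKNNParams()
        with pytest.raises(ContractError):
            build_hyperplane(np.array([np.nan, 1.0]), np.ones((3, 2)), p)


class TestHyperplaneDistance:
    def test_single_neighbor_closed_form(self):
        p = GHKNNParams()
        x = np.array([3.0, -1.0])
        hp = build_hyperplane(x, x[None, :], p)
        assert hyperplane_distance(x, hp, p) == pytest.approx((1 - 1 / 1.01) ** 2)

    def test_linear_mu0_equals_input_space_residual(self, rng):
        rows = rng.normal(size=(6, 4))
        x = rng.normal(size=4)
        p = GHKNNParams(lam=0.05, mu=0.0, k=4, kernel="linear")
        hp = build_hyperplane(x, rows, p)
        residual = (x - hp.centroid) - hp.centered.T @ hp.alpha
        assert hyperplane_distance(x, hp, p) == pytest.approx(residual @ residual)

    def test_invariant_to_neighbor_permutation(self, rng):
        rows = rng.normal(size=(5, 3))
        x = rng.normal(size=3)
        p = GHKNNParams(gamma=0.3, k=5)
        d1 = class_distance(x, rows, p)
        d2 = class_distance(x, rows[::-1].copy(), p)
        assert d1 == pytest.approx(d2, rel=1e-10)

    def test_nonnegative(self, rng):
        for _ in range(20):
            rows = rng.normal(size=(7, 4))
            x = rng.normal(size=4)
            p = GHKNNParams(gamma=0.5, mu=0.3, k=5)
            assert class_distance(x, rows, p) >= 0.0

    def test_monotone_in_lam(self, rng):
        grid = [1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0]
        for _ in range(15):
            d = int(rng.integers(2, 8))
            n = int(rng.integers(3, 8))
            rows = rng.normal(size=(n, d))
            x = rng.normal(size=d)
            mu = float(rng.uniform(0, 1))
            gamma = float(rng.uniform(0.01, 1))
            prev = -np.inf
            for lam in grid:
                p = GHKNNParams(lam=lam, gamma=gamma, mu=mu, k=n)
                dist = class_distance(x, rows, p)
                assert dist >= prev - 1e-12
                prev = dist


class TestHknnBaseline:
    def test_single_neighbor_exact_match(self):
        x = np.array([1.0, 2.0])
        for lam in (1e-6, 0.01, 5.0):
            assert hknn_distance(x, x[None, :], 1, lam) == pytest.approx(0.0, abs=1e-12)

    def test_affine_span_limit(self):
        # x on the segment between the two neighbours: distance -> 0 as lam -> 0
        rows = np.array([[0.0, 0.0], [2.0, 2.0]])
        x = np.array([1.0, 1.0])
        assert hknn_distance(x, rows, 2, 1e-10) == pytest.approx(0.0, abs=1e-8)

    def test_equivalence_with_linear_mu0_ghknn(self, rng):
        for _ in range(30):
            d = int(rng.integers(2, 10))
            n = int(rng.integers(3, 12))
            k = int(rng.integers(1, 8))
            rows = rng.normal(size=(n, d))
            x = rng.normal(size=d)
            lam = float(10 ** rng.uniform(-3, 0))
            p = GHKNNParams(lam=lam, mu=0.0, k=k, kernel="linear")
            assert class_distance(x, rows, p) == pytest.approx(
                hknn_distance(x, rows, k, lam), abs=1e-10
            )


class TestPredict:
    def _separated(self, rng, d=5, n=30, sep=20.0):
        a = rng.normal(size=(n, d))
        b = rng.normal(size=(n, d)) + sep / np.sqrt(d)
        return a, b

    def test_recovers_training_point_class(self, rng):
        a, b = self._separated(rng)
        train = {"A": a, "B": b}
        p = GHKNNParams(gamma=0.01, k=5)
        label, dists = predict(a[0], train, p)
        assert label == "A"
        assert dists["A"] < dists["B"]

    def test_mirror_tie_returns_first_label(self):
        x = np.zeros(2)
        a = np.array([[1.0, 0.0], [2.0, 0.0], [3.0, 0.0]])
        train = {"first": a, "second": -a}
        p = GHKNNParams(k=3)
        label, dists = predict(x, train, p)
        assert dists["first"] == pytest.approx(dists["second"])
        assert label == "first"

    def test_requires_two_classes(self):
        with pytest.raises(ContractError):
            predict(np.zeros(2), {"A": np.ones((3, 2))}, GHKNNParams())

    def test_agrees_with_hknn_on_random_data(self, rng):
        for _ in range(10):
            a = rng.normal(size=(10, 3))
            b = rng.normal(size=(10, 3)) + 1.0
            x = rng.normal(size=3)
            p = GHKNNParams(lam=0.01, mu=0.0, k=4, kernel="linear")
            label, _ = predict(x, {"A": a, "B": b}, p)
            hknn_label = min(
                [("A", hknn_distance(x, a, 4, 0.01)), ("B", hknn_distance(x, b, 4, 0.01))],
                key=lambda t: t[1],
            )[0]
            assert label == hknn_label

    def test_determinism(self, rng):
        a, b = self._separated(rng)
        X = rng.normal(size=(5, 5))
        clf = GHKNNClassifier(GHKNNParams(gamma=0.05))
        clf.fit(np.vstack([a, b]), np.array([0] * 30 + [1] * 30))
        y1 = clf.predict(X)
        y2 = clf.predict(X)
        np.testing.assert_array_equal(y1, y2)


class TestClassifier:
    def test_fit_predict_shapes(self, rng):
        X = rng.normal(size=(40, 4))
        y = np.array([0] * 20 + [1] * 20)
        clf = GHKNNClassifier().fit(X, y)
        labels, dists = clf.predict(X[:7], return_distances=True)
        assert labels.shape == (7,)
        assert dists.shape == (7, 2)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ContractError):
            GHKNNClassifier().fit(rng.normal(size=(5, 2)), np.ones(5))
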