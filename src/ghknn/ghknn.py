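"""Kernel local-hyperplane nearest-neighbour classification.

For a test point ``x`` and each class ``c`` the classifier

1. selects the ``k' = min(k, class size)`` class rows nearest to ``x``
   (input-space Euclidean distance, stable ties),
2. centres both the neighbours ``V`` and ``x`` on the neighbourhood
   centroid,
3. solves the positive-definite system
   ``(K(Vb, Vb) + lam*I + mu*L) alpha = K(Vb, xb)`` where ``L`` is the
   unnormalized graph Laplacian of the RBF similarity graph among the
   neighbours,
4. scores ``x`` by the squared kernel-space residual
   ``K(xb, xb) + alpha' K alpha - 2 K(Vb, xb)' alpha``

and predicts the class with the smallest residual.  With a linear kernel
and ``mu = 0`` this reduces exactly to the input-space local-hyperplane
baseline :func:`hknn_distance`.

Matrices here hold samples as rows (``V`` is k' x d).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.spatial.distance import cdist

from .exceptions import ConfigurationError, ContractError, NumericalError

_RESIDUAL_TOL = 1e-8
_NEGATIVE_DISTANCE_TOL = -1e-10

KERNELS = ("rbf", "linear")


@dataclass(frozen=True)
class GHKNNParams:
    """Classifier hyper-parameters.

    Defaults are the tuned operating point: ridge weight ``lam = 0.01``,
    RBF bandwidth ``gamma = 2**-15``, graph weight ``mu = 0.1``.
    """

    lam: float = 0.01
    gamma: float = 2.0 ** -15
    mu: float = 0.1
    k: int = 10
    kernel: str = "rbf"

    def __post_init__(self) -> None:
        problems = []
        if not self.lam > 0:
            problems.append(f"lam must be > 0, got {self.lam}")
        if not self.gamma > 0:
            problems.append(f"gamma must be > 0, got {self.gamma}")
        if self.mu < 0:
            problems.append(f"mu must be >= 0, got {self.mu}")
        if self.k < 1:
            problems.append(f"k must be a positive integer, got {self.k}")
        if self.kernel not in KERNELS:
            problems.append(f"kernel must be one of {KERNELS}, got {self.kernel!r}")
        if problems:
            raise ConfigurationError("; ".join(problems))


def rbf_kernel(xi: np.ndarray, xj: np.ndarray, gamma: float) -> float:
    """exp(-gamma * ||xi - xj||^2)."""
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    if xi.shape != xj.shape:
        raise ContractError(f"dimension mismatch: {xi.shape} vs {xj.shape}")
    return float(np.exp(-gamma * np.sum((xi - xj) ** 2)))


def _kernel_matrix(A: np.ndarray, B: np.ndarray, params: GHKNNParams) -> np.ndarray:
    if params.kernel == "rbf":
        return np.exp(-params.gamma * cdist(A, B, "sqeuclidean"))
    return A @ B.T


def _self_kernel(x: np.ndarray, params: GHKNNParams) -> float:
    return 1.0 if params.kernel == "rbf" else float(x @ x)


def select_neighbors(x: np.ndarray, class_rows: np.ndarray, k: int) -> np.ndarray:
    """Indices of the min(k, n) rows nearest to x; ties to the lower index."""
    rows = np.asarray(class_rows, dtype=float)
    if rows.ndim != 2 or rows.shape[0] == 0:
        raise ContractError("class_rows must be a non-empty 2-D matrix")
    d2 = np.sum((rows - np.asarray(x, dtype=float)) ** 2, axis=1)
    return np.argsort(d2, kind="stable")[: min(k, rows.shape[0])]


def build_graph_laplacian(V: np.ndarray, gamma: float) -> np.ndarray:
    """Unnormalized Laplacian L = D - W of the RBF graph over the rows of V.

    W has zero diagonal (no self loops); alpha' L alpha equals half the
    weighted sum of squared coefficient differences over ordered pairs.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2 or V.shape[0] < 1:
        raise ContractError("V must have at least one row")
    W = np.exp(-gamma * cdist(V, V, "sqeuclidean"))
    np.fill_diagonal(W, 0.0)
    return np.diag(W.sum(axis=1)) - W


@dataclass
class LocalHyperplane:
    """The per-class neighbourhood model fitted around one test point."""

    neighbors: np.ndarray          # (k', d) selected class rows
    centroid: np.ndarray           # (d,) neighbourhood mean
    centered: np.ndarray           # (k', d) neighbors - centroid
    laplacian: np.ndarray          # (k', k')
    alpha: np.ndarray | None = None
    _gram: np.ndarray | None = field(default=None, repr=False)


def build_hyperplane(
    x: np.ndarray, class_rows: np.ndarray, params: GHKNNParams
) -> LocalHyperplane:
    """Select neighbours of x within one class and solve the coefficients."""
    rows = np.asarray(class_rows, dtype=float)
    idx = select_neighbors(x, rows, params.k)
    V = rows[idx]
    centroid = V.mean(axis=0)
    hp = LocalHyperplane(
        neighbors=V,
        centroid=centroid,
        centered=V - centroid,
        laplacian=build_graph_laplacian(V, params.gamma),
    )
    hp.alpha = solve_alpha(x, hp, params)
    return hp


def solve_alpha(x: np.ndarray, hp: LocalHyperplane, params: GHKNNParams) -> np.ndarray:
    """Solve (K + lam*I + mu*L) alpha = K(Vb, xb); residual checked <= 1e-8."""
    x = np.asarray(x, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(hp.centered))):
        raise ContractError("non-finite inputs to solve_alpha")
    xb = x - hp.centroid
    K = _kernel_matrix(hp.centered, hp.centered, params)
    hp._gram = K
    b = _kernel_matrix(hp.centered, xb[None, :], params).ravel()
    A = K + params.lam * np.eye(K.shape[0]) + params.mu * hp.laplacian
    alpha = scipy.linalg.solve(A, b, assume_a="pos")
    residual = np.max(np.abs(A @ alpha - b))
    if residual > _RESIDUAL_TOL:
        raise NumericalError(f"linear solve residual {residual:.3e} > {_RESIDUAL_TOL}")
    return alpha


def hyperplane_distance(
    x: np.ndarray, hp: LocalHyperplane, params: GHKNNParams
) -> float:
    """Squared kernel-space distance from x to the local hyperplane."""
    if hp.alpha is None:
        raise ContractError("hyperplane has no solved alpha")
    x = np.asarray(x, dtype=float)
    xb = x - hp.centroid
    K = hp._gram
    if K is None:
        K = _kernel_matrix(hp.centered, hp.centered, params)
    b = _kernel_matrix(hp.centered, xb[None, :], params).ravel()
    dist = float(
        _self_kernel(xb, params) + hp.alpha @ K @ hp.alpha - 2.0 * b @ hp.alpha
    )
    if dist < _NEGATIVE_DISTANCE_TOL:
        raise NumericalError(f"hyperplane distance {dist:.3e} strongly negative")
    return max(dist, 0.0)


def class_distance(x: np.ndarray, class_rows: np.ndarray, params: GHKNNParams) -> float:
    """Distance from x to the local hyperplane of one class."""
    return hyperplane_distance(x, build_hyperplane(x, class_rows, params), params)


def predict(
    x: np.ndarray,
    train_by_class: dict,
    params: GHKNNParams,
) -> tuple[object, dict]:
    """Assign x to the class with the nearest local hyperplane.

    ``train_by_class`` maps label -> row matrix; its insertion order is the
    declared label order used for tie-breaking.  Returns the winning label
    and the per-class distance dict.
    """
    if len(train_by_class) < 2:
        raise ContractError("predict needs at least 2 classes")
    distances = {
        label: class_distance(x, rows, params)
        for label, rows in train_by_class.items()
    }
    best_label, best = None, np.inf
    for label, dist in distances.items():  # insertion order breaks ties
        if dist < best:
            best_label, best = label, dist
    return best_label, distances


def hknn_distance(x: np.ndarray, class_rows: np.ndarray, k: int, lam: float) -> float:
    """Input-space baseline: ||xb - V' alpha||^2 with ridge-solved alpha."""
    if not lam > 0:
        raise ConfigurationError(f"lam must be > 0, got {lam}")
    rows = np.asarray(class_rows, dtype=float)
    x = np.asarray(x, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(rows))):
        raise ContractError("non-finite inputs to hknn_distance")
    idx = select_neighbors(x, rows, k)
    V = rows[idx]
    centroid = V.mean(axis=0)
    Vb = V - centroid
    xb = x - centroid
    G = Vb @ Vb.T
    alpha = scipy.linalg.solve(G + lam * np.eye(G.shape[0]), Vb @ xb, assume_a="pos")
    r = xb - Vb.T @ alpha
    return float(r @ r)


class GHKNNClassifier:
    """Lazy (instance-based) classifier wrapping :func:`predict`.

    ``fit`` only stores the training rows grouped by label; the declared
    label order is the sorted unique-label order.
    """

    def __init__(self, params: GHKNNParams | None = None):
        self.params = params if params is not None else GHKNNParams()

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GHKNNClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ContractError("X must be (n, d) with one label per row")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ContractError("fit needs at least 2 classes")
        self._by_class = {label: X[y == label] for label in self.classes_}
        return self

    def predict(self, X: np.ndarray, return_distances: bool = False):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        labels = []
        dists = np.empty((X.shape[0], len(self.classes_)))
        for i, x in enumerate(X):
            label, dd = predict(x, self._by_class, self.params)
            labels.append(label)
            dists[i] = [dd[c] for c in self.classes_]
        labels = np.asarray(labels)
        if return_distances:
            return labels, dists
        return labels
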