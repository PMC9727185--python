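"""Minority-class oversampling by interpolation (SMOTE).

Each synthetic row is ``x + u * (x_n - x)`` for a minority row ``x``, one of
its k nearest minority neighbours ``x_n`` (Euclidean, ties broken by lower
row index) and ``u ~ U(0, 1)``.  All randomness flows from a single
``numpy.random.default_rng(seed)`` stream, so outputs are byte-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import ConfigurationError, ContractError

MATCH_MAJORITY = "match-majority"


@dataclass(frozen=True)
class ResampleConfig:
    k_neighbors: int = 5
    target_count: int | str = MATCH_MAJORITY
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ConfigurationError("k_neighbors must be a positive integer")
        if isinstance(self.target_count, str):
            if self.target_count not in (MATCH_MAJORITY, "match"):
                raise ConfigurationError(
                    f"target_count must be a positive integer or "
                    f"{MATCH_MAJORITY!r}, got {self.target_count!r}"
                )
        elif self.target_count < 1:
            raise ConfigurationError("target_count must be positive")


def _neighbor_table(X: np.ndarray, k: int) -> np.ndarray:
    """(n, k) indices of each row's k nearest other rows, stable ties."""
    n = X.shape[0]
    d2 = cdist(X, X, "sqeuclidean")
    order = np.argsort(d2, axis=1, kind="stable")
    not_self = order != np.arange(n)[:, None]
    return order[not_self].reshape(n, n - 1)[:, :k]


def smote_oversample(minority: np.ndarray, config: ResampleConfig) -> np.ndarray:
    """Return ``target_count - len(minority)`` synthetic rows.

    ``config.target_count`` must be an explicit integer here; resolving
    "match-majority" is :func:`balance_dataset`'s job.
    """
    X = np.asarray(minority, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ContractError("minority must be a non-empty 2-D matrix")
    n = X.shape[0]
    if isinstance(config.target_count, str):
        raise ConfigurationError(
            "smote_oversample needs an integer target_count; "
            "use balance_dataset for 'match-majority'"
        )
    if n < config.k_neighbors + 1:
        raise ConfigurationError(
            f"minority size {n} must exceed k_neighbors={config.k_neighbors}"
        )
    if config.target_count < n:
        raise ConfigurationError(
            f"target_count {config.target_count} below current count {n}"
        )
    n_new = config.target_count - n
    if n_new == 0:
        return np.zeros((0, X.shape[1]))

    neighbors = _neighbor_table(X, config.k_neighbors)
    rng = np.random.default_rng(config.seed)
    base = rng.integers(0, n, size=n_new)
    pick = rng.integers(0, config.k_neighbors, size=n_new)
    u = rng.random(size=n_new)
    chosen = neighbors[base, pick]
    return X[base] + u[:, None] * (X[chosen] - X[base])


def _balance_with_permutation(X: np.ndarray, y: np.ndarray, config: ResampleConfig):
    """Core of :func:`balance_dataset`; also returns the shuffle permutation
    (``perm[out_row] = source row`` in the pre-shuffle original+synthetic stack)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ContractError(f"balance_dataset needs binary labels, got {classes!r}")

    order = np.argsort(counts, kind="stable")
    minority_label = classes[order[0]]
    n_maj = counts[order[1]]
    target = int(n_maj) if isinstance(config.target_count, str) else config.target_count

    synthetic = smote_oversample(
        X[y == minority_label],
        dataclasses.replace(config, target_count=target),
    )
    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(len(synthetic), minority_label, dtype=y.dtype)])
    provenance = np.concatenate(
        [np.zeros(len(y), dtype=bool), np.ones(len(synthetic), dtype=bool)]
    )
    # separate stream so the shuffle does not perturb synthesis reproducibility
    perm = np.random.default_rng(config.seed + 1).permutation(len(y_out))
    return X_out[perm], y_out[perm], provenance[perm], perm


def balance_dataset(
    X: np.ndarray,
    y: np.ndarray,
    config: ResampleConfig,
    return_provenance: bool = False,
):
    """Oversample the minority class and reshuffle rows.

    The minority class is grown to ``config.target_count`` (or to the
    majority count for "match-majority"); majority rows are untouched; the
    combined rows are shuffled with the configured seed.  With
    ``return_provenance=True`` a boolean mask marking synthetic rows is
    appended to the return tuple.
    """
    X_out, y_out, provenance, _ = _balance_with_permutation(X, y, config)
    if return_provenance:
        return X_out, y_out, provenance
    return X_out, y_out
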