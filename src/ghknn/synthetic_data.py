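"""Seeded synthetic fixtures: biased sequence populations and Gaussian
feature clusters.

Sequence-level synthesis is the primary fixture so the featurization path is
exercised end to end; positives are enriched in a configurable residue set,
negatives are uniform, and ``bias_strength = 0`` makes the two populations
exchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ContractError
from .sequence_io import AMINO_ACIDS, ProteinRecord

#: Hydrophobic group of the shipped hydrophobicity partition.
DEFAULT_BIAS_RESIDUES = frozenset("CLVIMFW")


@dataclass(frozen=True)
class SyntheticSpec:
    n_pos: int
    n_neg: int
    length_range: tuple[int, int] = (50, 400)
    bias_residues: frozenset[str] = field(default=DEFAULT_BIAS_RESIDUES)
    bias_strength: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ContractError("n_pos and n_neg must be positive")
        lo, hi = self.length_range
        if lo < 2 or hi < lo:
            raise ContractError(f"invalid length_range {self.length_range}")
        if self.bias_strength < 0:
            raise ContractError("bias_strength must be >= 0")
        if not set(self.bias_residues) <= set(AMINO_ACIDS):
            raise ContractError("bias_residues must be standard residues")


def sample_sequence(
    length: int, residue_weights: np.ndarray, rng: np.random.Generator
) -> str:
    """i.i.d. residues from the normalized weight distribution.

    *residue_weights* is a length-20 array aligned with ``AMINO_ACIDS``.
    """
    if length < 2:
        raise ContractError(f"length must be >= 2, got {length}")
    w = np.asarray(residue_weights, dtype=float)
    if w.shape != (len(AMINO_ACIDS),) or np.any(w < 0) or not w.sum() > 0:
        raise ContractError("weights must be 20 non-negative values, not all zero")
    idx = rng.choice(len(AMINO_ACIDS), size=length, p=w / w.sum())
    return "".join(AMINO_ACIDS[i] for i in idx)


def generate_labeled_set(spec: SyntheticSpec) -> tuple[list[ProteinRecord], np.ndarray]:
    """n_pos biased positives (label 1) then n_neg uniform negatives (label 0)."""
    rng = np.random.default_rng(spec.seed)
    w_neg = np.ones(len(AMINO_ACIDS))
    w_pos = np.ones(len(AMINO_ACIDS))
    for i, aa in enumerate(AMINO_ACIDS):
        if aa in spec.bias_residues:
            w_pos[i] *= 1.0 + spec.bias_strength
    lo, hi = spec.length_range
    records = []
    for tag, count, weights in (("pos", spec.n_pos, w_pos), ("neg", spec.n_neg, w_neg)):
        for i in range(count):
            length = int(rng.integers(lo, hi + 1))
            records.append(
                ProteinRecord(
                    id=f"{tag}_{i:05d}",
                    sequence=sample_sequence(length, weights, rng),
                )
            )
    labels = np.concatenate([np.ones(spec.n_pos, dtype=int), np.zeros(spec.n_neg, dtype=int)])
    return records, labels


def generate_feature_clusters(
    n_per_class: int, dim: int, mean_shift: float, spread: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Two isotropic Gaussian clusters with centres *mean_shift* apart.

    The centres sit at +/- mean_shift/2 along the normalized all-ones
    direction, so their Euclidean separation is exactly *mean_shift*;
    *spread* is the per-coordinate standard deviation.  Label 0 rows come
    first, then label 1.
    """
    if dim < 1:
        raise ContractError("dim must be >= 1")
    if not spread > 0:
        raise ContractError("spread must be > 0")
    rng = np.random.default_rng(seed)
    direction = np.ones(dim) / np.sqrt(dim)
    offset = 0.5 * mean_shift * direction
    X0 = -offset + spread * rng.standard_normal((n_per_class, dim))
    X1 = offset + spread * rng.standard_normal((n_per_class, dim))
    X = np.vstack([X0, X1])
    y = np.concatenate([np.zeros(n_per_class, dtype=int), np.ones(n_per_class, dtype=int)])
    return X, y
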