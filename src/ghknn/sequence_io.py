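"""FASTA input, residue cleaning, and feature-table round-tripping.

Sequences are validated against the 20 standard amino-acid letters.
Nonstandard residues (B, J, O, U, X, Z, gaps, ``*``) are deleted rather than
remapped, and the record length used everywhere downstream is the cleaned
length.  Records shorter than 2 residues after cleaning are dropped because
the transition features need at least one adjacent pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .exceptions import ContractError, EmptyInputError, InvalidSequenceError

#: The 20 standard residues, in the fixed alphabetical order used for AAC.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_AA_SET = frozenset(AMINO_ACIDS)
_MIN_LENGTH = 2

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProteinRecord:
    """A named, validated protein sequence.

    Parameters
    ----------
    id : str
        Non-empty identifier (first whitespace-delimited FASTA header token).
    sequence : str
        Uppercase string over the 20-letter alphabet, length >= 2.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ContractError("record id must be a non-empty string")
        if len(self.sequence) < _MIN_LENGTH:
            raise InvalidSequenceError(
                f"sequence of record {self.id!r} has length "
                f"{len(self.sequence)} < {_MIN_LENGTH}"
            )
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise InvalidSequenceError(
                f"record {self.id!r} contains non-standard residues "
                f"{sorted(bad)}; pass the sequence through clean_sequence first"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


def clean_sequence(raw: str) -> str:
    """Uppercase *raw*, strip whitespace/'*', delete nonstandard residues.

    Raises
    ------
    InvalidSequenceError
        If nothing is left after cleaning.
    """
    if not raw:
        raise InvalidSequenceError("cannot clean an empty sequence")
    kept = []
    for ch in raw.upper():
        if ch.isspace() or ch == "*":
            continue
        if ch in _AA_SET:
            kept.append(ch)
        else:
            log.debug("dropping non-standard residue %r", ch)
    cleaned = "".join(kept)
    if not cleaned:
        raise InvalidSequenceError(f"sequence empty after cleaning: {raw!r}")
    return cleaned


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Parse a FASTA file into cleaned :class:`ProteinRecord` objects.

    Records whose cleaned sequence is shorter than 2 residues are dropped
    with a warning.  Raises :class:`EmptyInputError` if no usable record
    remains, and the underlying I/O error if the file cannot be read.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        try:
            seq = clean_sequence(str(entry.seq))
        except InvalidSequenceError:
            log.warning("dropping record %r: empty after cleaning", entry.id)
            continue
        if len(seq) < _MIN_LENGTH:
            log.warning(
                "dropping record %r: cleaned length %d < %d",
                entry.id, len(seq), _MIN_LENGTH,
            )
            continue
        records.append(ProteinRecord(id=entry.id, sequence=seq))
    if not records:
        raise EmptyInputError(f"no parseable records in {path}")
    return records


def _feature_columns(n_features: int) -> list[str]:
    return [f"f{i}" for i in range(1, n_features + 1)]


def write_feature_table(
    records: Sequence[ProteinRecord | str],
    vectors: np.ndarray,
    labels: Sequence,
    path: str | Path,
    delimiter: str = "\t",
) -> None:
    """Write an ``id, label, f1..fD`` delimited table.

    Floats are written with 17 significant digits so the table round-trips
    losslessly through :func:`read_feature_table`.
    """
    ids = [r.id if isinstance(r, ProteinRecord) else str(r) for r in records]
    X = np.asarray(vectors, dtype=float)
    if X.size == 0:
        X = X.reshape(0, X.shape[1] if X.ndim == 2 else 188)
    if X.ndim != 2:
        raise ContractError(f"vectors must be 2-D, got ndim={X.ndim}")
    if not (len(ids) == X.shape[0] == len(labels)):
        raise ContractError(
            f"length mismatch: {len(ids)} ids, {X.shape[0]} vectors, "
            f"{len(labels)} labels"
        )
    df = pd.DataFrame(X, columns=_feature_columns(X.shape[1]))
    df.insert(0, "label", list(labels))
    df.insert(0, "id", ids)
    df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")


def read_feature_table(
    path: str | Path, delimiter: str = "\t"
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Read a table written by :func:`write_feature_table`.

    Returns ``(ids, X, labels)`` with feature columns in f1..fD order.
    """
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    for col in ("id", "label"):
        if col not in df.columns:
            raise ContractError(f"feature table {path} lacks a {col!r} column")
    feat_cols = [c for c in df.columns if c not in ("id", "label")]
    ids = df["id"].astype(str).tolist()
    X = df[feat_cols].to_numpy(dtype=float)
    y = df["label"].to_numpy()
    return ids, X, y
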