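"""The 188-dimensional physicochemical sequence descriptor.

Layout (length 188):

* ``f1..f20`` — amino-acid composition (AAC), residues in the fixed order
  ``ACDEFGHIKLMNPQRSTVWY``.
* then, for each of 8 physicochemical properties in the order of the shipped
  group file (polarity, hydrophobicity, normalized van der Waals volume,
  polarizability, charge, secondary structure, solvent accessibility,
  surface tension): 3 composition + 15 distribution + 3 transition values,
  i.e. 21 features per property, 168 in total.

Each property partitions the 20 residues into three disjoint groups.  The
partitions are data, not code: they ship in ``data/ctd_groups.tsv`` and users
may point :func:`load_property_tables` at an edited copy to reproduce
alternative groupings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .exceptions import ConfigurationError, ContractError
from .sequence_io import AMINO_ACIDS, ProteinRecord

N_FEATURES = 188
N_AAC = 20
N_PROPERTIES = 8
FEATURES_PER_PROPERTY = 21  # 3 composition + 15 distribution + 3 transition

_AA_SET = frozenset(AMINO_ACIDS)
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# Quantile anchors for the distribution block: first occurrence, 25%, 50%,
# 75% and last occurrence of each group.
_QUANTILES = (0.25, 0.50, 0.75)


@dataclass(frozen=True)
class PropertyGroupTable:
    """A 3-way partition of the 20 standard residues for one property."""

    property_name: str
    groups: tuple[frozenset[str], frozenset[str], frozenset[str]]

    def __post_init__(self) -> None:
        if len(self.groups) != 3:
            raise ConfigurationError(
                f"{self.property_name}: expected 3 groups, got {len(self.groups)}"
            )
        union: set[str] = set()
        total = 0
        for g in self.groups:
            union |= g
            total += len(g)
        if total != len(union):
            raise ConfigurationError(
                f"{self.property_name}: groups are not pairwise disjoint"
            )
        if union != _AA_SET:
            raise ConfigurationError(
                f"{self.property_name}: groups must cover exactly the 20 "
                f"standard residues (missing {sorted(_AA_SET - union)}, "
                f"extra {sorted(union - _AA_SET)})"
            )

    def group_index(self) -> dict[str, int]:
        """Residue -> 0-based group index."""
        return {aa: i for i, g in enumerate(self.groups) for aa in g}


def load_property_tables(path: str | Path | None = None) -> tuple[PropertyGroupTable, ...]:
    """Load the 8 property partitions from a TSV file.

    The file has a header ``property  group1  group2  group3`` and one row
    per property; group cells are residue strings.  Exactly 8 rows are
    required, and their order fixes the feature layout.
    """
    if path is None:
        text = resources.files("ghknn").joinpath("data/ctd_groups.tsv").read_text()
    else:
        text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    tables = []
    for line in lines[1:]:
        cells = line.split("\t")
        if len(cells) != 4:
            raise ConfigurationError(f"malformed group-table row: {line!r}")
        name, g1, g2, g3 = cells
        tables.append(
            PropertyGroupTable(
                property_name=name.strip(),
                groups=(frozenset(g1.strip()), frozenset(g2.strip()), frozenset(g3.strip())),
            )
        )
    if len(tables) != N_PROPERTIES:
        raise ConfigurationError(
            f"expected {N_PROPERTIES} property rows, found {len(tables)}"
        )
    return tuple(tables)


@lru_cache(maxsize=1)
def default_tables() -> tuple[PropertyGroupTable, ...]:
    """The shipped 8-property partition set, cached."""
    return load_property_tables(None)


def _as_sequence(seq: ProteinRecord | str) -> str:
    if isinstance(seq, ProteinRecord):
        return seq.sequence
    rec = ProteinRecord(id="_", sequence=seq)  # reuse validation
    return rec.sequence


def aac_features(seq: ProteinRecord | str) -> np.ndarray:
    """Per-residue frequencies n_i / L, in ACDEFGHIKLMNPQRSTVWY order."""
    s = _as_sequence(seq)
    counts = np.zeros(N_AAC)
    for ch in s:
        counts[_AA_INDEX[ch]] += 1
    return counts / len(s)


def extract_aac_only(seq: ProteinRecord | str) -> np.ndarray:
    """Alias of :func:`aac_features` (the f1..f20 block on its own)."""
    return aac_features(seq)


def ctd_composition(seq: ProteinRecord | str, table: PropertyGroupTable) -> np.ndarray:
    """Fraction of residues falling in each of the three groups."""
    s = _as_sequence(seq)
    gidx = table.group_index()
    counts = np.zeros(3)
    for ch in s:
        counts[gidx[ch]] += 1
    return counts / len(s)


def ctd_distribution(seq: ProteinRecord | str, table: PropertyGroupTable) -> np.ndarray:
    """Positional distribution of each group: 5 values per group, 15 total.

    For group i with n_i occurrences at 1-based positions p_1 <= ... <= p_n,
    the 5 values are p at ranks ``1, max(1, ceil(q*n_i)) for q in
    (0.25, 0.5, 0.75), n_i`` divided by the sequence length; all 0 when the
    group does not occur.
    """
    s = _as_sequence(seq)
    length = len(s)
    gidx = table.group_index()
    positions: list[list[int]] = [[], [], []]
    for pos, ch in enumerate(s, start=1):
        positions[gidx[ch]].append(pos)
    out = np.zeros(15)
    for i, occ in enumerate(positions):
        n_i = len(occ)
        if n_i == 0:
            continue
        ranks = [1] + [max(1, math.ceil(q * n_i)) for q in _QUANTILES] + [n_i]
        out[5 * i : 5 * i + 5] = [occ[r - 1] / length for r in ranks]
    return out


def ctd_transition(seq: ProteinRecord | str, table: PropertyGroupTable) -> np.ndarray:
    """Cross-group adjacent-pair frequencies for pairs (1,2), (1,3), (2,3).

    Each adjacent residue pair with its two members in different groups
    counts once, regardless of order; the denominator is L - 1.
    """
    s = _as_sequence(seq)
    gidx = table.group_index()
    idx = np.fromiter((gidx[ch] for ch in s), dtype=np.int64, count=len(s))
    a, b = idx[:-1], idx[1:]
    differ = a != b
    # group-index sums 1, 2, 3 identify the unordered pairs (0,1), (0,2), (1,2)
    # once same-group pairs are masked out
    sums = (a + b)[differ]
    counts = np.array([(sums == 1).sum(), (sums == 2).sum(), (sums == 3).sum()])
    return counts / (len(s) - 1)


def extract_188d(
    seq: ProteinRecord | str,
    tables: Sequence[PropertyGroupTable] | None = None,
) -> np.ndarray:
    """The full 188-value descriptor for one sequence."""
    if tables is None:
        tables = default_tables()
    if len(tables) != N_PROPERTIES:
        raise ConfigurationError(
            f"extract_188d needs exactly {N_PROPERTIES} property tables, "
            f"got {len(tables)}"
        )
    blocks = [aac_features(seq)]
    for table in tables:
        blocks.append(ctd_composition(seq, table))
        blocks.append(ctd_distribution(seq, table))
        blocks.append(ctd_transition(seq, table))
    vec = np.concatenate(blocks)
    assert vec.shape == (N_FEATURES,)
    return vec


def extract_many(
    records: Iterable[ProteinRecord | str],
    tables: Sequence[PropertyGroupTable] | None = None,
    descriptor: str = "188d",
) -> np.ndarray:
    """Stack descriptors for many sequences into an (n, D) matrix."""
    if descriptor == "188d":
        rows = [extract_188d(r, tables) for r in records]
        width = N_FEATURES
    elif descriptor == "aac":
        rows = [aac_features(r) for r in records]
        width = N_AAC
    else:
        raise ContractError(f"unknown descriptor {descriptor!r}")
    if not rows:
        return np.zeros((0, width))
    return np.vstack(rows)
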