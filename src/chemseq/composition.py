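"""Group composition vectors and the pairwise chemical dissimilarity matrix.

For a sequence ``S_i`` of length ``L_i`` the count of residues falling in
group ``G_k`` is ``S_i(T_k)`` and the score per hundred is

    S_i(G_k) = S_i(T_k) / L_i * 100 .

The dissimilarity between two sequences is the L1 distance between their
8-dimensional percent vectors,

    D_ij = sum_k | S_i(G_k) - S_j(G_k) | ,

which is bounded by 200 (two disjoint compositions) and is a metric on
percent vectors. Percentages are kept at full floating precision
internally; reports round to 4 decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .alphabet import (
    CHEMICAL_GROUPS,
    STANDARD_AMINO_ACIDS,
    AminoAcidSequence,
    NonstandardResidueError,
    ReducedSequence,
)

__all__ = [
    "AminoAcidCountVector",
    "GroupCompositionVector",
    "DissimilarityMatrix",
    "count_amino_acids",
    "group_composition",
    "composition_from_counts",
    "dissimilarity",
    "dissimilarity_matrix",
]

#: fixed column order for 20-dim count vectors (groups in code order)
AMINO_ACID_ORDER: tuple[str, ...] = tuple(
    aa for g in CHEMICAL_GROUPS for aa in sorted(g.members)
)


@dataclass(frozen=True)
class AminoAcidCountVector:
    """Per-amino-acid occurrence counts for one sequence."""

    id: str
    counts: Mapping[str, int]
    length: int

    def __post_init__(self):
        unknown = set(self.counts) - STANDARD_AMINO_ACIDS
        if unknown:
            raise ValueError(f"{self.id!r}: nonstandard keys {sorted(unknown)}")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError(f"{self.id!r}: negative counts")
        total = sum(self.counts.values())
        if total != self.length:
            raise ValueError(
                f"{self.id!r}: counts sum to {total}, stated length {self.length}"
            )
        if self.length <= 0:
            raise ValueError(f"{self.id!r}: length must be positive")


@dataclass(frozen=True)
class GroupCompositionVector:
    """Per-group counts and percent scores for one sequence."""

    id: str
    counts: tuple[int, ...]  # 8 non-negative integers, sum = length
    length: int

    def __post_init__(self):
        if len(self.counts) != 8:
            raise ValueError("exactly 8 group counts required")
        if any(c < 0 for c in self.counts):
            raise ValueError(f"{self.id!r}: negative group counts")
        if sum(self.counts) != self.length:
            raise ValueError(
                f"{self.id!r}: group counts sum to {sum(self.counts)}, "
                f"stated length {self.length}"
            )
        if self.length <= 0:
            raise ValueError(f"{self.id!r}: length must be positive")

    @property
    def percents(self) -> np.ndarray:
        """Scores per hundred, one per group; sums to 100."""
        return np.asarray(self.counts, dtype=float) / self.length * 100.0


def count_amino_acids(seq: AminoAcidSequence) -> AminoAcidCountVector:
    """Tally each standard residue in the sequence.

    Nonstandard residues raise :class:`NonstandardResidueError` (this
    operation feeds compositions, where silent coercion would corrupt
    every downstream number).
    """
    counts: dict[str, int] = {}
    for pos, aa in enumerate(seq.residues, start=1):
        if aa not in STANDARD_AMINO_ACIDS:
            raise NonstandardResidueError(aa, pos)
        counts[aa] = counts.get(aa, 0) + 1
    return AminoAcidCountVector(id=seq.id, counts=counts, length=len(seq))


def group_composition(reduced: ReducedSequence) -> GroupCompositionVector:
    """Group counts and percent scores of a reduced sequence."""
    counts = [0] * 8
    for code in reduced.codes:
        counts[code - 1] += 1
    return GroupCompositionVector(
        id=reduced.id, counts=tuple(counts), length=len(reduced)
    )


def composition_from_counts(aa_counts: AminoAcidCountVector) -> GroupCompositionVector:
    """Group composition from a 20-dim count vector (no sequence needed).

    Group counts are the sums of member amino acid counts under the
    8-group partition; lets printed count tables drive the composition
    and dissimilarity computations directly.
    """
    counts = tuple(
        sum(aa_counts.counts.get(aa, 0) for aa in g.members)
        for g in CHEMICAL_GROUPS
    )
    return GroupCompositionVector(
        id=aa_counts.id, counts=counts, length=aa_counts.length
    )


def dissimilarity(a: GroupCompositionVector, b: GroupCompositionVector) -> float:
    """L1 distance between two group percent vectors (percent units)."""
    return float(np.abs(a.percents - b.percents).sum())


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric matrix of pairwise chemical dissimilarities (percent units)."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("dissimilarity matrix must have a zero diagonal")
        if np.any(v < 0) or np.any(v > 200):
            raise ValueError("entries must lie in [0, 200]")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])


def dissimilarity_matrix(
    vectors: Sequence[GroupCompositionVector],
) -> DissimilarityMatrix:
    """All-pairs dissimilarity of ≥2 composition vectors with unique ids."""
    if len(vectors) < 2:
        raise ValueError("at least two composition vectors required")
    ids = [v.id for v in vectors]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate sequence ids: {ids}")
    P = np.stack([v.percents for v in vectors])  # n x 8
    D = np.abs(P[:, None, :] - P[None, :, :]).sum(axis=2)
    np.fill_diagonal(D, 0.0)
    return DissimilarityMatrix(labels=tuple(ids), values=D)
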