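"""Chemical pattern search over the reduced group alphabet.

A reduced pattern is a word over the codes 1..8 (written as a digit
string, e.g. "624621"). Matching is against the *group* codes of a
sequence, optionally tolerating a bounded number of group mismatches;
mismatch positions are reported 1-based within the pattern, matching the
convention of conserved-block tables that bold the deviating residue.

Alignment-free discovery: the k-mers (over group codes) occurring exactly
in every member of a sequence set, and the k-mers conserved in one set
but absent from every member of a contrasted set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .alphabet import ReducedSequence

__all__ = [
    "ReducedPattern",
    "PatternHit",
    "find_pattern",
    "conserved_kmers",
    "group_specific_kmers",
    "residue_conserved_indices",
]


@dataclass(frozen=True, order=True)
class ReducedPattern:
    """A pattern over group codes 1..8."""

    codes: tuple[int, ...]

    def __post_init__(self):
        if not self.codes:
            raise ValueError("empty pattern")
        if any(not 1 <= c <= 8 for c in self.codes):
            raise ValueError(f"pattern codes out of range 1..8: {self.codes}")

    @classmethod
    def from_string(cls, digits: str) -> "ReducedPattern":
        return cls(tuple(int(d) for d in digits))

    def __len__(self) -> int:
        return len(self.codes)

    def __str__(self) -> str:
        return "".join(map(str, self.codes))


@dataclass(frozen=True)
class PatternHit:
    """One window of a sequence matching a pattern within the mismatch budget.

    ``start`` is the 1-based position of the window in the (unaligned)
    sequence; ``mismatch_positions`` are 1-based indices *within the
    pattern* where the residue's group differs from the pattern code.
    """

    sequence_id: str
    start: int
    matched_residues: str
    mismatch_positions: tuple[int, ...]


def find_pattern(
    reduced: ReducedSequence, p: ReducedPattern, max_mismatch: int = 0
) -> list[PatternHit]:
    """All windows of the sequence within ``max_mismatch`` group mismatches.

    Hits are sorted by start. ``matched_residues`` carries the amino acid
    window when the reduced sequence retains its source, else the group
    digit string of the window.
    """
    k = len(p)
    if k > len(reduced):
        raise ValueError(
            f"pattern length {k} exceeds sequence length {len(reduced)}"
        )
    codes = reduced.codes
    residues = reduced.source.residues if reduced.source is not None else None
    hits: list[PatternHit] = []
    for start in range(len(codes) - k + 1):
        mismatches = tuple(
            i + 1 for i in range(k) if codes[start + i] != p.codes[i]
        )
        if len(mismatches) <= max_mismatch:
            window = (
                residues[start : start + k]
                if residues is not None
                else "".join(map(str, codes[start : start + k]))
            )
            hits.append(
                PatternHit(
                    sequence_id=reduced.id,
                    start=start + 1,
                    matched_residues=window,
                    mismatch_positions=mismatches,
                )
            )
    return hits


def residue_conserved_indices(hits: Sequence[PatternHit]) -> tuple[int, ...]:
    """Pattern indices (1-based) where every hit carries the identical residue.

    Secondary annotation on top of group-level matching: given one hit per
    sequence for the same pattern, the returned indices are conserved at
    the amino acid level, not merely chemically.
    """
    if not hits:
        raise ValueError("at least one hit required")
    k = len(hits[0].matched_residues)
    if any(len(h.matched_residues) != k for h in hits):
        raise ValueError("hits must come from one pattern (equal window length)")
    return tuple(
        i + 1
        for i in range(k)
        if len({h.matched_residues[i] for h in hits}) == 1
    )


def _kmer_set(reduced: ReducedSequence, k: int) -> set[ReducedPattern]:
    codes = reduced.codes
    return {
        ReducedPattern(codes[i : i + k]) for i in range(len(codes) - k + 1)
    }


def conserved_kmers(
    sequences: Sequence[ReducedSequence], k: int
) -> set[ReducedPattern]:
    """Reduced k-mers occurring exactly in every input sequence."""
    if not sequences:
        raise ValueError("at least one sequence required")
    if k < 1:
        raise ValueError("k must be >= 1")
    if any(len(s) < k for s in sequences):
        raise ValueError(f"all sequences must have length >= k = {k}")
    return set.intersection(*(_kmer_set(s, k) for s in sequences))


def group_specific_kmers(
    group_a: Sequence[ReducedSequence],
    group_b: Sequence[ReducedSequence],
    k: int,
) -> tuple[set[ReducedPattern], set[ReducedPattern]]:
    """K-mers conserved in one group and absent from every member of the other."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    union_a = set.union(*(_kmer_set(s, k) for s in group_a))
    union_b = set.union(*(_kmer_set(s, k) for s in group_b))
    specific_a = conserved_kmers(group_a, k) - union_b
    specific_b = conserved_kmers(group_b, k) - union_a
    return specific_a, specific_b
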