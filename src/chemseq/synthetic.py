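"""Seeded generation of test sequences with controlled group composition,
plus the packaged reference tables for the five c7-type cytochromes.

The generator emulates only the group-level structure that drives every
computation in this package: per-group residue counts (or target
percents, rounded to counts by largest remainder). Residues within a
group are drawn uniformly and the whole sequence is shuffled, so no
positional structure (heme-binding motifs, signal peptides) is emulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from .alphabet import CHEMICAL_GROUPS, AminoAcidSequence

__all__ = ["CompositionSpec", "generate_sequence", "load_fixture"]

_FIXTURES = ("table1_lengths", "table3_counts", "table8_patterns")


@dataclass(frozen=True)
class CompositionSpec:
    """Target composition for one synthetic sequence.

    Exactly one of ``counts`` (8 integers summing to ``length``) or
    ``percents`` (8 reals summing to 100) must be given. In percent mode
    the counts are obtained by largest-remainder rounding of
    percent × length / 100.
    """

    length: int
    counts: Optional[tuple[int, ...]] = None
    percents: Optional[tuple[float, ...]] = None
    seed: int = 0
    id: str = "synthetic"

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(f"length must be positive, got {self.length}")
        if (self.counts is None) == (self.percents is None):
            raise ValueError("give exactly one of counts or percents")
        if self.counts is not None:
            if len(self.counts) != 8 or any(c < 0 for c in self.counts):
                raise ValueError("counts must be 8 non-negative integers")
            if sum(self.counts) != self.length:
                raise ValueError(
                    f"counts sum to {sum(self.counts)}, length is {self.length}"
                )
        else:
            if len(self.percents) != 8 or any(p < 0 for p in self.percents):
                raise ValueError("percents must be 8 non-negative reals")
            if abs(sum(self.percents) - 100.0) > 1e-9:
                raise ValueError(
                    f"percents must sum to 100, got {sum(self.percents)}"
                )

    def resolved_counts(self) -> tuple[int, ...]:
        """Per-group counts; largest-remainder rounding in percent mode."""
        if self.counts is not None:
            return self.counts
        exact = np.asarray(self.percents, dtype=float) * self.length / 100.0
        floors = np.floor(exact).astype(int)
        shortfall = self.length - int(floors.sum())
        # hand the leftover residues to the largest fractional remainders;
        # ties go to the lower group code for determinism
        order = np.lexsort((np.arange(8), -(exact - floors)))
        for k in order[:shortfall]:
            floors[k] += 1
        return tuple(int(c) for c in floors)


def generate_sequence(
    spec: CompositionSpec, rng: Optional[np.random.Generator] = None
) -> AminoAcidSequence:
    """Random sequence whose group counts exactly match the spec.

    Within each group residues are drawn uniformly; the concatenation is
    then shuffled. The generator is an explicit seeded engine (``rng``,
    defaulting to ``np.random.default_rng(spec.seed)``) — identical seed,
    identical sequence.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    counts = spec.resolved_counts()
    residues: list[str] = []
    for group, n in zip(CHEMICAL_GROUPS, counts):
        members = sorted(group.members)
        residues.extend(rng.choice(members, size=n))
    rng.shuffle(residues)
    return AminoAcidSequence(id=spec.id, residues="".join(residues))


def load_fixture(name: str) -> list[dict]:
    """Parse one of the packaged reference tables into records.

    ``table1_lengths``: id, length, chain_start, chain_end, accession per
    sequence. ``table3_counts``: id, length and the 20 per-amino-acid
    counts. ``table8_patterns``: pattern digit string, id, 1-based
    position and the matched residue block.
    """
    if name not in _FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {_FIXTURES}")
    text = (
        resources.files("chemseq").joinpath(f"data/{name}.tsv").read_text()
    )
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    header = lines[0].split("\t")
    records = []
    for ln in lines[1:]:
        rec: dict = dict(zip(header, ln.split("\t")))
        for key, val in rec.items():
            if val.lstrip("-").isdigit() and key not in ("pattern", "id"):
                rec[key] = int(val)
        records.append(rec)
    return records


def cytochrome_count_vectors():
    """The five reference per-amino-acid count vectors as package objects."""
    from .composition import AminoAcidCountVector

    out = []
    for rec in load_fixture("table3_counts"):
        seq_id = rec.pop("id")
        length = rec.pop("length")
        out.append(
            AminoAcidCountVector(
                id=seq_id,
                counts={aa: int(c) for aa, c in rec.items()},
                length=length,
            )
        )
    return out
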