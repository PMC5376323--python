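"""Reduced chemical-group alphabet for protein sequences.

The 20 standard amino acids are partitioned into eight side-chain chemistry
classes, numbered 1..8:

====  ==================  =================
code  name                members
====  ==================  =================
1     Acidic              D, E
2     Basic               R, H, K
3     Aromatic            Y, F, W
4     Aliphatic           I, L, V, A, G
5     Cyclic              P
6     SulfurContaining    M, C
7     HydroxylContaining  S, T
8     AcidicAmide         Q, N
====  ==================  =================

A protein sequence re-expressed over this alphabet (a :class:`ReducedSequence`)
is the substrate for every downstream computation in this package: group
composition vectors, order-pair digraphs, cycle subdomains and chemical
pattern search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "ChemicalGroup",
    "CHEMICAL_GROUPS",
    "STANDARD_AMINO_ACIDS",
    "AminoAcidSequence",
    "ReducedSequence",
    "NonstandardResidueError",
    "encode_residue",
    "encode_sequence",
    "decode_group",
]


@dataclass(frozen=True)
class ChemicalGroup:
    """One of the eight side-chain chemistry classes."""

    code: int
    name: str
    members: frozenset[str]


CHEMICAL_GROUPS: tuple[ChemicalGroup, ...] = (
    ChemicalGroup(1, "Acidic", frozenset("DE")),
    ChemicalGroup(2, "Basic", frozenset("RHK")),
    ChemicalGroup(3, "Aromatic", frozenset("YFW")),
    ChemicalGroup(4, "Aliphatic", frozenset("ILVAG")),
    ChemicalGroup(5, "Cyclic", frozenset("P")),
    ChemicalGroup(6, "SulfurContaining", frozenset("MC")),
    ChemicalGroup(7, "HydroxylContaining", frozenset("ST")),
    ChemicalGroup(8, "AcidicAmide", frozenset("QN")),
)

#: residue -> group code lookup, derived from the partition above
GROUP_OF: dict[str, int] = {
    aa: g.code for g in CHEMICAL_GROUPS for aa in g.members
}

STANDARD_AMINO_ACIDS: frozenset[str] = frozenset(GROUP_OF)

# the eight member sets must partition the 20 standard residues exactly
assert len(STANDARD_AMINO_ACIDS) == 20
assert sum(len(g.members) for g in CHEMICAL_GROUPS) == 20


class NonstandardResidueError(ValueError):
    """A residue outside the 20-letter standard alphabet was encountered.

    Carries the offending character and its 1-based position (0 when the
    residue was checked in isolation).
    """

    def __init__(self, residue: str, position: int = 0):
        self.residue = residue
        self.position = position
        where = f" at position {position}" if position else ""
        super().__init__(
            f"nonstandard residue {residue!r}{where}: not one of the 20 "
            "standard amino acids"
        )


@dataclass(frozen=True)
class AminoAcidSequence:
    """A named protein sequence over the standard 20-letter alphabet.

    Residues are uppercased on construction; positions are 1-based
    throughout the package. Validation of the alphabet itself happens at
    encoding time so that the nonstandard-residue policy (error vs skip)
    is applied in one place.
    """

    id: str
    residues: str

    def __post_init__(self):
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ReducedSequence:
    """A protein sequence re-expressed as group codes 1..8.

    ``codes`` is position-parallel to the source residues (when no residues
    were dropped). ``dropped_positions`` records 1-based source positions
    removed under the skip-nonstandard policy.
    """

    id: str
    codes: tuple[int, ...]
    source: Optional[AminoAcidSequence] = None
    dropped_positions: tuple[int, ...] = field(default=())

    def __post_init__(self):
        if not self.codes:
            raise ValueError(f"reduced sequence {self.id!r} is empty")
        bad = [c for c in self.codes if not 1 <= c <= 8]
        if bad:
            raise ValueError(f"group codes out of range 1..8: {bad[:5]}")
        if self.source is not None and not self.dropped_positions:
            if len(self.codes) != len(self.source):
                raise ValueError(
                    f"{self.id!r}: {len(self.codes)} codes for "
                    f"{len(self.source)} residues"
                )

    def __len__(self) -> int:
        return len(self.codes)

    def __str__(self) -> str:
        return "".join(map(str, self.codes))

    @classmethod
    def from_codes(cls, codes: Iterable[int], id: str = "") -> "ReducedSequence":
        """Build directly from an iterable of group codes (or a digit string)."""
        if isinstance(codes, str):
            codes = (int(c) for c in codes)
        return cls(id=id, codes=tuple(codes))


def encode_residue(aa: str) -> int:
    """Map a one-letter amino acid code to its chemical group code 1..8.

    Raises
    ------
    NonstandardResidueError
        For anything outside the 20 standard codes (B, J, O, U, X, Z,
        gaps, ...). Gap characters are always an error here: alignment
        handling is out of scope for this alphabet.
    """
    aa = aa.upper()
    try:
        return GROUP_OF[aa]
    except KeyError:
        raise NonstandardResidueError(aa) from None


def encode_sequence(
    seq: AminoAcidSequence, *, on_nonstandard: str = "error"
) -> ReducedSequence:
    """Encode a full sequence position-wise into group codes.

    Parameters
    ----------
    seq : AminoAcidSequence
        Input sequence (non-empty, uppercased on construction).
    on_nonstandard : {"error", "skip"}
        Policy for residues outside the standard alphabet. ``"error"``
        (default) raises :class:`NonstandardResidueError` naming the
        character and its 1-based position. ``"skip"`` drops such
        positions and records them in ``dropped_positions`` — note that
        downstream position reports then refer to the *retained* residues.
    """
    if on_nonstandard not in ("error", "skip"):
        raise ValueError(f"unknown nonstandard-residue policy {on_nonstandard!r}")
    codes: list[int] = []
    dropped: list[int] = []
    for pos, aa in enumerate(seq.residues, start=1):
        code = GROUP_OF.get(aa)
        if code is None:
            if on_nonstandard == "error":
                raise NonstandardResidueError(aa, pos)
            dropped.append(pos)
        else:
            codes.append(code)
    if not codes:
        raise ValueError(
            f"sequence {seq.id!r}: no standard residues remain after skipping"
        )
    return ReducedSequence(
        id=seq.id,
        codes=tuple(codes),
        source=seq,
        dropped_positions=tuple(dropped),
    )


def decode_group(code: int) -> ChemicalGroup:
    """Inverse lookup: group code 1..8 to its name and member set."""
    if not isinstance(code, int) or not 1 <= code <= 8:
        raise ValueError(f"group code must be an integer in 1..8, got {code!r}")
    return CHEMICAL_GROUPS[code - 1]
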