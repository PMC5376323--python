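"""FASTA input and TSV/Newick/DOT/JSON report writers.

All residue coordinates in every output are 1-based inclusive.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

from Bio import SeqIO

from .alphabet import AminoAcidSequence, ReducedSequence
from .composition import DissimilarityMatrix, GroupCompositionVector
from .cycles import Cycle, SubdomainWindow
from .digraph import OrderPairDigraph
from .linkage import Dendrogram
from .patterns import PatternHit

__all__ = [
    "read_fasta",
    "write_reduced",
    "write_composition_tsv",
    "write_dissimilarity_tsv",
    "write_merge_table",
    "write_adjacency_tsv",
    "write_edge_positions_tsv",
    "write_cycle_report",
    "write_pattern_hits",
    "write_json_summary",
]

SUMMARY_SCHEMA_VERSION = 1


def read_fasta(path: str | Path) -> list[AminoAcidSequence]:
    """Ordered records from a FASTA file; ids are the first header token.

    Wrapped lines and CRLF endings are handled by the underlying parser.
    Empty files, duplicate ids and empty records are errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    seqs = [AminoAcidSequence(id=r.id, residues=str(r.seq)) for r in records]
    ids = [s.id for s in seqs]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate sequence ids in {path}: {sorted(dupes)}")
    return seqs


def write_reduced(reduced: ReducedSequence, digits_path: Path, tsv_path: Path) -> None:
    """Digit-string and 2-column (position, code) TSV forms of a reduced sequence."""
    digits_path.write_text(str(reduced) + "\n")
    lines = ["position\tcode"]
    lines += [f"{i}\t{c}" for i, c in enumerate(reduced.codes, start=1)]
    tsv_path.write_text("\n".join(lines) + "\n")


def write_composition_tsv(
    vectors: Sequence[GroupCompositionVector], path: Path
) -> None:
    header = "id\t" + "\t".join(f"G{k}" for k in range(1, 9))
    lines = [header]
    for v in vectors:
        lines.append(v.id + "\t" + "\t".join(f"{p:.4f}" for p in v.percents))
    path.write_text("\n".join(lines) + "\n")


def write_dissimilarity_tsv(D: DissimilarityMatrix, path: Path) -> None:
    lines = ["id\t" + "\t".join(D.labels)]
    for lbl, row in zip(D.labels, D.values):
        lines.append(lbl + "\t" + "\t".join(f"{x:.4f}" for x in row))
    path.write_text("\n".join(lines) + "\n")


def write_merge_table(t: Dendrogram, path: Path) -> None:
    lines = ["step\tcluster_a\tcluster_b\theight"]
    for step, m in enumerate(t.merges, start=1):
        lines.append(
            f"{step}\t{','.join(m.cluster_a)}\t{','.join(m.cluster_b)}"
            f"\t{m.height:.4f}"
        )
    path.write_text("\n".join(lines) + "\n")


def write_adjacency_tsv(g: OrderPairDigraph, path: Path, *, binary: bool = True) -> None:
    mat = g.adjacency if binary else g.multiplicity
    lines = ["node\t" + "\t".join(str(k) for k in range(1, 9))]
    for u in range(1, 9):
        lines.append(str(u) + "\t" + "\t".join(str(x) for x in mat[u - 1]))
    path.write_text("\n".join(lines) + "\n")


def write_edge_positions_tsv(g: OrderPairDigraph, path: Path) -> None:
    lines = ["edge\tpositions"]
    for (u, v) in sorted(g.positions):
        pos = ",".join(map(str, g.positions[(u, v)]))
        lines.append(f"{u}{v}\t{pos}")
    path.write_text("\n".join(lines) + "\n")


def write_cycle_report(
    rows: Sequence[tuple[Cycle, dict[str, bool], list[SubdomainWindow]]],
    path: Path,
) -> None:
    """One row per cycle: canonical string, length, presence flags, windows."""
    seq_ids = sorted(rows[0][1]) if rows else []
    lines = ["cycle\tlength\t" + "\t".join(seq_ids) + "\twindows"]
    for cycle, presence, windows in rows:
        flags = "\t".join("1" if presence[s] else "0" for s in seq_ids)
        spans = ";".join(f"{w.sequence_id}:{w.start}-{w.end}" for w in windows)
        lines.append(f"{cycle}\t{cycle.length}\t{flags}\t{spans}")
    path.write_text("\n".join(lines) + "\n")


def write_pattern_hits(hits: Sequence[PatternHit], pattern: str, path: Path) -> None:
    lines = ["id\tstart\tresidues\tpattern\tmismatch_positions"]
    for h in hits:
        mm = ",".join(map(str, h.mismatch_positions))
        lines.append(f"{h.sequence_id}\t{h.start}\t{h.matched_residues}\t{pattern}\t{mm}")
    path.write_text("\n".join(lines) + "\n")


def write_json_summary(summary: dict, path: Path) -> None:
    payload = {"schema_version": SUMMARY_SCHEMA_VERSION, **summary}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
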