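"""Bounded simple-cycle enumeration and cycle-to-subdomain mapping.

A simple directed cycle visits each intermediate node once; its length is
its edge count. On an order-pair digraph (≤8 nodes) cycles of length 3–6
are the default objects of interest. Each cycle is held in a canonical
rotation starting at its smallest node code, so rotations of the same
directed cycle compare equal.

A cycle is *present* in a digraph when every one of its edges is in the
digraph's edge set — presence is edge-set-wise, not a contiguous
traversal of the sequence. The residue span realizing a cycle (its
subdomain window) is therefore the smallest window containing at least
one occurrence of every cycle edge; when edges repeat, several candidate
windows exist and only the minimal ones (containing no other candidate)
are reported.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import networkx as nx

from .digraph import Edge, OrderPairDigraph, edge_set, to_networkx

__all__ = ["Cycle", "SubdomainWindow", "enumerate_cycles", "unique_cycles",
           "cycle_subdomains"]


@dataclass(frozen=True, order=True)
class Cycle:
    """A simple directed cycle in canonical rotation.

    ``nodes`` lists the visited nodes once, starting at the smallest code,
    without repeating the first node at the end — the cycle 7→2→1→6→4→5→7
    is stored as (1, 6, 4, 5, 7, 2) and prints as "164572"-style digit
    strings via ``str()``.
    """

    nodes: tuple[int, ...]

    def __post_init__(self):
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError(f"nodes repeat within cycle {self.nodes}")
        object.__setattr__(self, "nodes", _canonical_rotation(self.nodes))

    @property
    def length(self) -> int:
        """Edge count (equals node count for a simple cycle)."""
        return len(self.nodes)

    @property
    def edges(self) -> tuple[Edge, ...]:
        n = self.nodes
        return tuple((n[i], n[(i + 1) % len(n)]) for i in range(len(n)))

    def __str__(self) -> str:
        return "".join(map(str, self.nodes))


def _canonical_rotation(nodes: tuple[int, ...]) -> tuple[int, ...]:
    k = nodes.index(min(nodes))
    return nodes[k:] + nodes[:k]


@dataclass(frozen=True)
class SubdomainWindow:
    """1-based inclusive residue span within which every cycle edge occurs."""

    sequence_id: str
    start: int
    end: int
    edge_positions: tuple[tuple[Edge, int], ...]

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"window start {self.start} > end {self.end}")


def enumerate_cycles(
    g: OrderPairDigraph, min_len: int = 3, max_len: int = 6
) -> frozenset[Cycle]:
    """All simple directed cycles of g with min_len ≤ length ≤ max_len.

    Length 1 means a self-loop, length 2 a back-and-forth pair; the
    defaults 3..6 exclude both. Bounds outside 1..8 are rejected (a simple
    cycle cannot exceed the 8 available nodes).
    """
    if not (1 <= min_len <= max_len <= 8):
        raise ValueError(f"invalid cycle length bounds {min_len}..{max_len}")
    G = to_networkx(g)
    found = (
        Cycle(tuple(c))
        for c in nx.simple_cycles(G, length_bound=max_len)
        if len(c) >= min_len
    )
    return frozenset(found)


def _cycle_present(c: Cycle, g: OrderPairDigraph) -> bool:
    return set(c.edges) <= edge_set(g)


def unique_cycles(
    group_a: Sequence[OrderPairDigraph],
    group_b: Sequence[OrderPairDigraph],
    min_len: int = 3,
    max_len: int = 6,
) -> tuple[frozenset[Cycle], frozenset[Cycle]]:
    """Cycles present in every member of one group and no member of the other."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")

    def _unique(own: Sequence[OrderPairDigraph], other: Sequence[OrderPairDigraph]):
        shared = frozenset.intersection(
            *(enumerate_cycles(g, min_len, max_len) for g in own)
        )
        return frozenset(
            c for c in shared if not any(_cycle_present(c, g) for g in other)
        )

    return _unique(group_a, group_b), _unique(group_b, group_a)


def cycle_subdomains(c: Cycle, g: OrderPairDigraph) -> list[SubdomainWindow]:
    """Minimal residue windows of g's sequence realizing the cycle.

    For every combination of one occurrence position per cycle edge the
    candidate window is [min position, max position + 1] (the +1 covers
    the target residue of the last pair). Candidates containing another
    candidate are dropped; survivors are returned sorted by start.
    """
    if not _cycle_present(c, g):
        raise ValueError(f"cycle {c} is not present in digraph {g.id!r}")
    per_edge = [(e, g.positions[e]) for e in c.edges]
    candidates: list[SubdomainWindow] = []
    for combo in itertools.product(*(pos for _, pos in per_edge)):
        candidates.append(
            SubdomainWindow(
                sequence_id=g.id,
                start=min(combo),
                end=max(combo) + 1,
                edge_positions=tuple((e, p) for (e, _), p in zip(per_edge, combo)),
            )
        )
    minimal = [
        w
        for w in candidates
        if not any(
            (v.start >= w.start and v.end <= w.end and (v.start, v.end) != (w.start, w.end))
            for v in candidates
        )
    ]
    # distinct spans only, keeping the first realization of each
    seen: dict[tuple[int, int], SubdomainWindow] = {}
    for w in sorted(minimal, key=lambda w: (w.start, w.end)):
        seen.setdefault((w.start, w.end), w)
    return list(seen.values())
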