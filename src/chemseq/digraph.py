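"""Order-pair directed graph of a reduced sequence.

Reading the reduced sequence T as consecutive ordered pairs
(T(i), T(i+1)) yields a directed graph on at most eight nodes (the group
codes present). The classic construction records only edge presence — a
binary 8×8 adjacency matrix; this module additionally records how many
times each ordered pair occurs and at which 1-based source positions,
which downstream cycle-subdomain mapping needs ("some edges are repeating
more than once" across a sequence).

Edge-set comparison across two sets of homologous sequences reports the
edges present in every member of one side and absent from every member of
the other (group-unique edges), plus the edges common to all.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .alphabet import ReducedSequence, decode_group

__all__ = [
    "OrderPairDigraph",
    "EdgeComparison",
    "build_digraph",
    "edge_set",
    "compare_edge_sets",
    "to_networkx",
    "to_dot",
]

Edge = tuple[int, int]


@dataclass(frozen=True)
class OrderPairDigraph:
    """Directed graph of consecutive group-code pairs of one sequence.

    ``adjacency`` is the binary 8×8 presence matrix (index 0 ↔ code 1);
    ``multiplicity`` counts occurrences of each ordered pair and sums to
    L−1 for a length-L sequence; ``positions`` maps each edge to the
    1-based positions of its source residue. Self-loops are legal edges.
    """

    id: str
    adjacency: np.ndarray
    multiplicity: np.ndarray
    positions: Mapping[Edge, tuple[int, ...]]
    nodes: frozenset[int]

    def __post_init__(self):
        adj = np.asarray(self.adjacency, dtype=int)
        mult = np.asarray(self.multiplicity, dtype=int)
        object.__setattr__(self, "adjacency", adj)
        object.__setattr__(self, "multiplicity", mult)
        if adj.shape != (8, 8) or mult.shape != (8, 8):
            raise ValueError("adjacency and multiplicity must be 8x8")
        if not np.array_equal(adj, (mult > 0).astype(int)):
            raise ValueError("adjacency must be the binarized multiplicity")


@dataclass(frozen=True)
class EdgeComparison:
    """Unique and common edges between two groups of digraphs.

    ``unique_to_a``: edges in every member of A and in no member of B;
    symmetrically for ``unique_to_b``. ``common_to_all``: edges present
    in every member of A ∪ B.
    """

    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    unique_to_a: frozenset[Edge]
    unique_to_b: frozenset[Edge]
    common_to_all: frozenset[Edge]


def build_digraph(reduced: ReducedSequence) -> OrderPairDigraph:
    """Scan consecutive ordered pairs of the reduced sequence into a digraph."""
    codes = reduced.codes
    if len(codes) < 2:
        raise ValueError(
            f"{reduced.id!r}: length {len(codes)} has no consecutive pairs"
        )
    mult = np.zeros((8, 8), dtype=int)
    positions: dict[Edge, list[int]] = {}
    for i, (u, v) in enumerate(zip(codes, codes[1:]), start=1):
        mult[u - 1, v - 1] += 1
        positions.setdefault((u, v), []).append(i)
    return OrderPairDigraph(
        id=reduced.id,
        adjacency=(mult > 0).astype(int),
        multiplicity=mult,
        positions={e: tuple(p) for e, p in positions.items()},
        nodes=frozenset(codes),
    )


def edge_set(g: OrderPairDigraph) -> frozenset[Edge]:
    """Ordered pairs with adjacency 1 (≤64 possible)."""
    return frozenset(g.positions)


def compare_edge_sets(
    group_a: Sequence[OrderPairDigraph], group_b: Sequence[OrderPairDigraph]
) -> EdgeComparison:
    """Group-unique and universally common edges between two digraph sets."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    sets_a = [edge_set(g) for g in group_a]
    sets_b = [edge_set(g) for g in group_b]
    inter_a = frozenset.intersection(*sets_a)
    inter_b = frozenset.intersection(*sets_b)
    union_a = frozenset.union(*sets_a)
    union_b = frozenset.union(*sets_b)
    return EdgeComparison(
        group_a=tuple(g.id for g in group_a),
        group_b=tuple(g.id for g in group_b),
        unique_to_a=inter_a - union_b,
        unique_to_b=inter_b - union_a,
        common_to_all=inter_a & inter_b,
    )


def to_networkx(g: OrderPairDigraph) -> nx.DiGraph:
    """Binary-adjacency view as a networkx DiGraph (nodes are codes 1..8)."""
    G = nx.DiGraph()
    G.add_nodes_from(sorted(g.nodes))
    for (u, v), pos in g.positions.items():
        G.add_edge(u, v, multiplicity=len(pos))
    return G


def to_dot(g: OrderPairDigraph) -> str:
    """DOT serialization; node labels carry the group code and name."""
    lines = [f'digraph "{g.id}" {{']
    for code in sorted(g.nodes):
        name = decode_group(code).name
        lines.append(f'  {code} [label="{code}: {name}"];')
    for (u, v) in sorted(g.positions):
        lines.append(f"  {u} -> {v};")
    lines.append("}")
    return "\n".join(lines)
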