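"""Single-linkage (nearest distance) tree from a dissimilarity matrix.

Agglomerative clustering with inter-cluster distance equal to the minimum
pairwise entry between members. Single linkage is monotone, so merge
heights are non-decreasing and the dendrogram is ultrametric: the height
of the lowest common ancestor of two leaves never exceeds their pairwise
dissimilarity.

The merge loop is written out explicitly rather than delegated so that
the tie-break is pinned down: when several cluster pairs share the
minimal distance, the pair with the lexicographically smallest (i, j)
active-cluster indices merges first. Heights are in the same percent
units as the input matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .composition import DissimilarityMatrix

__all__ = ["Dendrogram", "Merge", "single_linkage", "to_newick"]


@dataclass(frozen=True)
class Merge:
    """One agglomeration step: two clusters (as sorted leaf tuples) and its height."""

    cluster_a: tuple[str, ...]
    cluster_b: tuple[str, ...]
    height: float


@dataclass(frozen=True)
class Dendrogram:
    """Result of single-linkage clustering: n leaves, n−1 ordered merges."""

    leaves: tuple[str, ...]
    merges: tuple[Merge, ...]

    def __post_init__(self):
        if len(self.merges) != len(self.leaves) - 1:
            raise ValueError(
                f"{len(self.leaves)} leaves require {len(self.leaves) - 1} "
                f"merges, got {len(self.merges)}"
            )
        heights = [m.height for m in self.merges]
        if any(b < a - 1e-9 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def heights(self) -> tuple[float, ...]:
        return tuple(m.height for m in self.merges)


def single_linkage(D: DissimilarityMatrix) -> Dendrogram:
    """Cluster the matrix agglomeratively by nearest distance.

    Raises ``ValueError`` for matrices that fail the dissimilarity-matrix
    invariants (asymmetry, negative entries) — those are enforced by
    :class:`DissimilarityMatrix` itself — or have fewer than two labels.
    """
    n = len(D.labels)
    if n < 2:
        raise ValueError("need at least two items to cluster")
    # active clusters as sorted tuples of leaf labels, keyed by creation order
    clusters: list[tuple[str, ...]] = [(lbl,) for lbl in D.labels]
    # inter-cluster distances, single linkage: start from the leaf matrix
    dist = {
        (i, j): float(D.values[i, j])
        for i in range(n)
        for j in range(i + 1, n)
    }
    merges: list[Merge] = []
    active = list(range(n))
    next_id = n
    members: dict[int, tuple[str, ...]] = {i: clusters[i] for i in range(n)}
    while len(active) > 1:
        # smallest distance; ties broken by lexicographically smallest (i, j)
        (i, j) = min(
            ((a, b) for ia, a in enumerate(active) for b in active[ia + 1 :]),
            key=lambda ij: (dist[ij], ij),
        )
        h = dist[(i, j)]
        merged = tuple(sorted(members[i] + members[j]))
        merges.append(Merge(members[i], members[j], h))
        members[next_id] = merged
        active = [k for k in active if k not in (i, j)]
        for k in active:
            dij = dist.get((min(i, k), max(i, k)))
            djk = dist.get((min(j, k), max(j, k)))
            dist[(k, next_id)] = min(dij, djk)
        active.append(next_id)
        next_id += 1
    return Dendrogram(leaves=D.labels, merges=tuple(merges))


def to_newick(t: Dendrogram) -> str:
    """Serialize as rooted binary Newick with ultrametric branch lengths.

    Branch lengths are half the height difference between parent and
    child (leaves sit at height 0), so leaf-to-leaf path lengths display
    the merge heights of a standard dendrogram. Raw heights are also
    available from ``t.merges``.
    """
    reprs: dict[tuple[str, ...], tuple[str, float]] = {
        (leaf,): (leaf, 0.0) for leaf in t.leaves
    }
    newick = ""
    for m in t.merges:
        ra, ha = reprs.pop(m.cluster_a)
        rb, hb = reprs.pop(m.cluster_b)
        la = (m.height - ha) / 2.0
        lb = (m.height - hb) / 2.0
        newick = f"({ra}:{la:g},{rb}:{lb:g})"
        reprs[tuple(sorted(m.cluster_a + m.cluster_b))] = (newick, m.height)
    return newick + ";"
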