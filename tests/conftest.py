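import numpy as np
import pytest

import chemseq as cs


@pytest.fixture(scope="session")
def cyto_counts():
    """The five reference c7 cytochrome per-amino-acid count vectors."""
    return cs.cytochrome_count_vectors()


@pytest.fixture(scope="session")
def cyto_vectors(cyto_counts):
    return [cs.composition_from_counts(v) for v in cyto_counts]


@pytest.fixture(scope="session")
def cyto_matrix(cyto_vectors):
    return cs.dissimilarity_matrix(cyto_vectors)


@pytest.fixture()
def rng():
    return np.random.default_rng(20170331)


def random_reduced(rng, length=None, id="rand"):
    """Random reduced sequence over codes 1..8."""
    if length is None:
        length = int(rng.integers(2, 120))
    return cs.ReducedSequence.from_codes(rng.integers(1, 9, size=length), id=id)


def random_digraph_edges(rng, max_nodes=8, p=0.35):
    """Random edge set over a random subset of the 8 group codes."""
    k = int(rng.integers(2, max_nodes + 1))
    nodes = rng.choice(np.arange(1, 9), size=k, replace=False)
    return {
        (int(u), int(v))
        for u in nodes
        for v in nodes
        if rng.random() < p
    }


def digraph_from_edges(edges, id="g"):
    """Build an OrderPairDigraph carrying exactly the given edge set.

    Positions are synthetic (one occurrence per edge, arbitrary order);
    only edge-set-level behavior should be asserted on the result.
    """
    mult = np.zeros((8, 8), dtype=int)
    positions = {}
    for i, (u, v) in enumerate(sorted(edges), start=1):
        mult[u - 1, v - 1] = 1
        positions[(u, v)] = (i,)
    nodes = frozenset(u for e in edges for u in e)
    return cs.OrderPairDigraph(
        id=id,
        adjacency=(mult > 0).astype(int),
        multiplicity=mult,
        positions=positions,
        nodes=nodes,
    )
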