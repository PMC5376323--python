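import itertools
import math

import pytest

import chemseq as cs
from chemseq.cycles import Cycle
from conftest import digraph_from_edges, random_digraph_edges


def brute_force_cycles(edges, min_len, max_len):
    """Exhaustive DFS-from-every-start enumeration of simple cycles.

    Independent of the package: its own adjacency walk and its own
    canonicalization (rotation to the minimum node).
    """

    def canonical(path):
        k = path.index(min(path))
        return path[k:] + path[:k]

    adj = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
    found = set()

    def dfs(start, path):
        for v in adj.get(path[-1], ()):
            if v == start:
                if min_len <= len(path) <= max_len:
                    found.add(canonical(tuple(path)))
            elif v not in path and len(path) < max_len:
                dfs(start, path + [v])

    for s in adj:
        dfs(s, [s])
    return found


def complete_digraph(n):
    return digraph_from_edges(
        {(u, v) for u in range(1, n + 1) for v in range(1, n + 1) if u != v},
        id=f"K{n}",
    )


def test_canonical_form_is_rotation_invariant_and_idempotent():
    c = Cycle((7, 2, 1, 6, 4, 5))
    assert c.nodes == (1, 6, 4, 5, 7, 2)
    assert str(c) == "164572"
    for k in range(6):
        rotated = Cycle(c.nodes[k:] + c.nodes[:k])
        assert rotated == c
    assert Cycle(c.nodes) == c
    assert c.length == 6
    assert c.edges[-1] == (2, 1)


def test_repeated_nodes_are_rejected():
    with pytest.raises(ValueError):
        Cycle((1, 2, 1, 3))


def test_triangle_graph_single_cycle():
    g = digraph_from_edges({(2, 3), (3, 6), (6, 2)}, "tri")
    cycles = cs.enumerate_cycles(g, 3, 6)
    assert cycles == {Cycle((2, 3, 6))}
    assert str(next(iter(cycles))) == "236"


def test_complete_three_node_digraph_has_two_directed_triangles():
    cycles = cs.enumerate_cycles(complete_digraph(3), 3, 3)
    assert cycles == {Cycle((1, 2, 3)), Cycle((1, 3, 2))}


@pytest.mark.parametrize("k,expected", [(3, 112), (4, 420), (5, 1344), (6, 3360)])
def test_complete_eight_node_counts_match_closed_form(k, expected):
    # C(8,k) * (k-1)! directed simple cycles of length k
    assert expected == math.comb(8, k) * math.factorial(k - 1)
    assert len(cs.enumerate_cycles(complete_digraph(8), k, k)) == expected


def test_complete_eight_node_total_for_default_bounds():
    assert len(cs.enumerate_cycles(complete_digraph(8), 3, 6)) == 5236


def test_invalid_bounds_are_rejected():
    g = complete_digraph(3)
    for bad in [(0, 3), (4, 3), (3, 9)]:
        with pytest.raises(ValueError):
            cs.enumerate_cycles(g, *bad)


def test_enumeration_matches_brute_force_on_random_digraphs(rng):
    for _ in range(200):
        edges = random_digraph_edges(rng)
        if not edges:
            continue
        g = digraph_from_edges(edges, "r")
        ours = {c.nodes for c in cs.enumerate_cycles(g, 3, 6)}
        assert ours == brute_force_cycles(edges, 3, 6)


def test_enumeration_with_min_len_one_includes_self_loops(rng):
    g = digraph_from_edges({(4, 4), (1, 2), (2, 1)}, "loops")
    cycles = cs.enumerate_cycles(g, 1, 6)
    assert Cycle((4,)) in cycles
    assert Cycle((1, 2)) in cycles


def test_unique_cycles_basic_contrast():
    a = [digraph_from_edges({(1, 2), (2, 3), (3, 1)}, "a")]
    b = [digraph_from_edges({(1, 2), (2, 1)}, "b")]
    ua, ub = cs.unique_cycles(a, b, 3, 6)
    assert ua == {Cycle((1, 2, 3))}
    assert ub == frozenset()
    # swapping the groups swaps the outputs
    ub2, ua2 = cs.unique_cycles(b, a, 3, 6)
    assert (ua2, ub2) == (ua, ub)


def test_unique_cycles_matches_brute_force_membership(rng):
    for _ in range(50):
        a = [digraph_from_edges(random_digraph_edges(rng), f"a{i}") for i in range(2)]
        b = [digraph_from_edges(random_digraph_edges(rng), f"b{i}") for i in range(2)]
        ua, ub = cs.unique_cycles(a, b, 3, 6)

        def present(cycle_nodes, g):
            es = cs.edge_set(g)
            n = cycle_nodes
            return all(
                (n[i], n[(i + 1) % len(n)]) in es for i in range(len(n))
            )

        all_candidates = set()
        for g in a + b:
            all_candidates |= brute_force_cycles(cs.edge_set(g), 3, 6)
        expect_a = {
            c for c in all_candidates
            if all(present(c, g) for g in a) and not any(present(c, g) for g in b)
        }
        expect_b = {
            c for c in all_candidates
            if all(present(c, g) for g in b) and not any(present(c, g) for g in a)
        }
        assert {c.nodes for c in ua} == expect_a
        assert {c.nodes for c in ub} == expect_b


def test_subdomain_single_occurrence_edges_give_one_window():
    # cycle 2->3->6->2 realized by pairs at source positions 13, 30, 47
    codes = [4] * 100
    codes[12:14] = [2, 3]
    codes[29:31] = [3, 6]
    codes[46:48] = [6, 2]
    g = cs.build_digraph(cs.ReducedSequence.from_codes(codes, id="s"))
    windows = cs.cycle_subdomains(Cycle((2, 3, 6)), g)
    assert len(windows) == 1
    assert (windows[0].start, windows[0].end) == (13, 48)


def test_subdomains_keep_only_minimal_windows(rng):
    """With repeated edges, windows match exhaustive combination search."""
    for _ in range(50):
        codes = list(rng.integers(1, 5, size=40))
        g = cs.build_digraph(cs.ReducedSequence.from_codes(codes, id="s"))
        cycles = cs.enumerate_cycles(g, 3, 4)
        for c in itertools.islice(cycles, 3):
            windows = cs.cycle_subdomains(c, g)
            assert windows
            # oracle: all candidate spans from the cartesian product
            spans = set()
            for combo in itertools.product(*(g.positions[e] for e in c.edges)):
                spans.add((min(combo), max(combo) + 1))
            minimal = {
                w for w in spans
                if not any(
                    v != w and v[0] >= w[0] and v[1] <= w[1] for v in spans
                )
            }
            assert {(w.start, w.end) for w in windows} == minimal
            # every reported window re-scanned contains every cycle edge
            for w in windows:
                for (u, v) in c.edges:
                    assert any(
                        w.start <= p <= w.end - 1
                        and codes[p - 1] == u and codes[p] == v
                        for p in g.positions[(u, v)]
                    )
                assert w.start <= w.end


def test_absent_cycle_is_an_error():
    g = cs.build_digraph(cs.ReducedSequence.from_codes([1, 2, 1], id="s"))
    with pytest.raises(ValueError):
        cs.cycle_subdomains(Cycle((1, 2, 3)), g)
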