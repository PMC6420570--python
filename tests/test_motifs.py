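"""Triad classification and induced census."""

import itertools

import networkx as nx
import numpy as np
import pytest

from motifweb import motifs
from motifweb.motifs import (
    CODE16_TABLE,
    MOTIF_CODES,
    MOTIF_TO_TRIAD,
    TRIAD16,
    census_adjacency,
    census_profile,
    classify_triad,
)
from motifweb.webs import build_probabilistic_web

from conftest import brute_force_census, random_digraph


@pytest.mark.parametrize(
    "edges,expected",
    [
        ([("A", "B"), ("B", "C")], "s1"),  # tri-trophic chain
        ([("A", "B"), ("B", "C"), ("A", "C")], "s2"),  # omnivory
        ([("A", "B"), ("B", "C"), ("C", "A")], "s3"),  # loop
        ([("A", "C"), ("B", "C")], "s4"),  # apparent competition
        ([("A", "B"), ("A", "C")], "s5"),  # exploitative competition
        ([("A", "B"), ("B", "A"), ("C", "A")], "d1"),
        ([("A", "B"), ("B", "A"), ("A", "C"), ("C", "A"), ("B", "C"), ("C", "B")], "d8"),
    ],
)
def test_classify_named_motifs(edges, expected):
    assert classify_triad(edges) == expected


def test_single_edge_is_disconnected():
    assert classify_triad([("A", "B")], nodes=["A", "B", "C"]) == "disconnected"
    assert classify_triad([("A", "B"), ("B", "A")], nodes="ABC") == "disconnected"


def test_classify_rejects_self_loop_and_bad_nodes():
    with pytest.raises(ValueError, match="self-loop"):
        classify_triad([("A", "A"), ("B", "C")], nodes="ABC")
    with pytest.raises(ValueError, match="3 nodes"):
        classify_triad([("A", "B")])


def test_relabeling_invariance():
    rng = np.random.default_rng(5)
    for _ in range(50):
        code = int(rng.integers(64))
        pairs = [(0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)]
        edges = [pairs[b] for b in range(6) if code >> b & 1]
        base = classify_triad(edges, nodes=range(3))
        for perm in itertools.permutations(range(3)):
            relabeled = [(perm[u], perm[v]) for u, v in edges]
            assert classify_triad(relabeled, nodes=range(3)) == base


def test_motif_triad_mapping_agrees_with_networkx():
    """The shipped motif->triad-type table matches an independent census."""
    for code, name16 in MOTIF_TO_TRIAD.items():
        edges = motifs._edges_of(
            [c for c in range(64) if TRIAD16[CODE16_TABLE[c]] == name16][0]
        )
        g = nx.DiGraph(list(edges))
        g.add_nodes_from(range(3))
        cen = nx.triadic_census(g)
        hits = [k for k, v in cen.items() if v == 1 and k != "003"]
        assert hits == [name16], (code, name16, hits)


@pytest.mark.parametrize("n,p,seed", [(6, 0.2, 0), (9, 0.4, 1), (12, 0.15, 2), (8, 0.7, 3)])
def test_census_equals_bruteforce(n, p, seed):
    adj = random_digraph(n, p, np.random.default_rng(seed))
    expected, disc = brute_force_census(adj)
    got = census_adjacency(adj)
    assert dict(zip(MOTIF_CODES, got.tolist())) == expected
    # conservation: all classes plus disconnected triples account for C(n,3)
    assert got.sum() + disc == n * (n - 1) * (n - 2) // 6


def test_census_chain_star_empty():
    chain = np.zeros((4, 4), np.uint8)
    chain[0, 1] = chain[1, 2] = chain[2, 3] = 1
    c = dict(zip(MOTIF_CODES, census_adjacency(chain).tolist()))
    assert c["s1"] == 2 and sum(c.values()) == 2

    star = np.zeros((4, 4), np.uint8)
    star[1, 0] = star[2, 0] = star[3, 0] = 1
    c = dict(zip(MOTIF_CODES, census_adjacency(star).tolist()))
    assert c["s4"] == 3 and sum(c.values()) == 3

    assert census_adjacency(np.zeros((5, 5), np.uint8)).sum() == 0


def test_census_permutation_invariance():
    rng = np.random.default_rng(11)
    adj = random_digraph(15, 0.25, rng)
    base = census_adjacency(adj)
    for _ in range(5):
        perm = rng.permutation(15)
        assert np.array_equal(census_adjacency(adj[np.ix_(perm, perm)]), base)


def test_census_rejects_self_loops():
    adj = np.eye(4, dtype=np.uint8)
    with pytest.raises(ValueError, match="elf-loop"):
        census_adjacency(adj)


def _deterministic_pweb(small_pool, small_design):
    from motifweb.webs import ScalarConfig

    sample = small_design.samples[-1]
    pweb = build_probabilistic_web(
        sample, small_pool.nodes, small_pool.links, ScalarConfig(100, 10000)
    )
    pweb.A = (pweb.A > 0.5).astype(float)  # make sampling deterministic
    return pweb


def test_census_profile_deterministic_web(small_pool, small_design):
    """With A in {0,1} every iteration samples the same web."""
    pweb = _deterministic_pweb(small_pool, small_design)
    full1, free1, grounded = census_profile(pweb, iterations=1, global_seed=0)
    full3, free3, _ = census_profile(pweb, iterations=3, global_seed=0)
    assert np.array_equal(full1.counts, full3.counts)
    assert np.array_equal(free1.counts, free3.counts)
    # free-floating counts can never exceed full-web counts
    assert np.all(free1.counts <= full1.counts)
    ok = full1.counts > 0
    assert np.allclose(
        grounded[ok], (full1.counts[ok] - free1.counts[ok]) / full1.counts[ok]
    )


def test_census_profile_seed_determinism(small_pool, small_design):
    from motifweb.webs import ScalarConfig

    sample = small_design.samples[3]
    pweb = build_probabilistic_web(
        sample, small_pool.nodes, small_pool.links, ScalarConfig(100, 10000)
    )
    a = census_profile(pweb, iterations=2, global_seed=42)
    b = census_profile(pweb, iterations=2, global_seed=42)
    assert np.array_equal(a[0].counts, b[0].counts)
    assert np.array_equal(a[1].counts, b[1].counts)
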