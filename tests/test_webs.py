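"""Interaction probabilities, sampling, sub-webs, calibration."""

import numpy as np
import pytest

from motifweb.community import CommunityValidationError, MetawebLink, Node, PlotSample
from motifweb.webs import (
    ScalarConfig,
    build_probabilistic_web,
    calibrate_scalars,
    consumer_subweb,
    diversity_scaled_scalars,
    encounter_probability,
    interaction_probability,
    median_omnivore_generality,
    sample_binary_web,
)


@pytest.mark.parametrize(
    "link_type,res_role,n_i,n_j,expected",
    [
        (1, "plant", 0.01, 0.01, 1.0),  # specific literature record
        (2, "consumer", 0.01, 0.01, 1.0),  # generalised record, mobile resource
        (3, "static_resource", 0.0, 0.5, 1.0),  # ubiquitous static resource
        (3, "plant", 0.2, 0.05, 0.1),  # alpha * n_i * n_j with alpha = 10
        (2, "plant", 0.5, 0.5, 1.0),  # 10 * 0.25 = 2.5 clipped at 1
        (4, "consumer", 0.1, 0.1, 1.0),  # beta = 1000: 10 clipped at 1
        (5, "consumer", 0.01, 0.01, 0.1),  # beta * n_i * n_j = 0.1
    ],
)
def test_encounter_probability_cases(link_type, res_role, n_i, n_j, expected):
    sc = ScalarConfig(alpha=10.0, beta=1000.0)
    assert encounter_probability(link_type, res_role, n_i, n_j, sc) == pytest.approx(expected)


def test_unknown_link_type_rejected():
    with pytest.raises(CommunityValidationError):
        encounter_probability(6, "plant", 0.1, 0.1, ScalarConfig(1, 1))


def test_interaction_probability_wrapper():
    plant = Node("p", "plant")
    bug = Node("c", "consumer", "herbivore", "herb", 3.0)
    link = MetawebLink("p", "c", 1)
    assert interaction_probability(link, plant, bug, 0.3, 0.2, ScalarConfig(1, 1)) == 1.0
    with pytest.raises(CommunityValidationError):
        interaction_probability(link, bug, plant, 0.3, 0.2, ScalarConfig(1, 1))


def _two_level_model():
    nodes = {
        "p1": Node("p1", "plant"),
        "p2": Node("p2", "plant"),
        "h1": Node("h1", "consumer", "herbivore", "herb", 3.0),
        "c1": Node("c1", "consumer", "predator", "herb", 8.0),
    }
    links = [
        MetawebLink("p1", "h1", 1),
        MetawebLink("p2", "h1", 3),
        MetawebLink("h1", "c1", 4),
    ]
    sample = PlotSample(
        "P1", "B1", 1, 2,
        plant_cover={"p1": 0.3, "p2": 0.3},
        consumer_abundance={"h1": 10, "c1": 5},
    )
    return nodes, links, sample


def test_build_support_matches_metaweb_restriction():
    nodes, links, sample = _two_level_model()
    pweb = build_probabilistic_web(sample, nodes, links, ScalarConfig(10, 10))
    idx = {nid: k for k, nid in enumerate(pweb.node_ids)}
    support = {(r, c) for r in pweb.node_ids for c in pweb.node_ids
               if pweb.A[idx[r], idx[c]] > 0}
    cooccur = set(pweb.node_ids)
    expected = {(l.resource_id, l.consumer_id) for l in links
                if l.resource_id in cooccur and l.consumer_id in cooccur}
    assert support == expected
    assert np.all(np.diagonal(pweb.A) == 0)
    assert pweb.A.min() >= 0 and pweb.A.max() <= 1


def test_absent_consumer_excluded():
    nodes, links, sample = _two_level_model()
    sample.consumer_abundance["c1"] = 0
    pweb = build_probabilistic_web(sample, nodes, links, ScalarConfig(10, 10))
    assert "c1" not in pweb.node_ids


def test_monophagous_type1_block():
    nodes, links, sample = _two_level_model()
    sample.plant_cover = {"p1": 0.5}
    sample.consumer_abundance = {"h1": 4}
    pweb = build_probabilistic_web(sample, nodes, links, ScalarConfig(10, 10))
    idx = {nid: k for k, nid in enumerate(pweb.node_ids)}
    assert pweb.A[idx["p1"], idx["h1"]] == 1.0


def test_degenerate_plot_rejected():
    nodes, links, _ = _two_level_model()
    empty = PlotSample("P9", "B1", 1, 2)
    with pytest.raises(CommunityValidationError, match="degenerate"):
        build_probabilistic_web(empty, nodes, links, ScalarConfig(1, 1))


def test_saturated_scalars_fill_support():
    """alpha, beta -> infinity puts probability 1 on every supported link."""
    nodes, links, sample = _two_level_model()
    pweb = build_probabilistic_web(sample, nodes, links, ScalarConfig(1e12, 1e12))
    assert set(np.unique(pweb.A)) <= {0.0, 1.0}
    assert (pweb.A == 1).sum() == 3


def test_sampling_extremes_and_pruning():
    nodes, links, sample = _two_level_model()
    pweb = build_probabilistic_web(sample, nodes, links, ScalarConfig(1e12, 1e12))
    bweb = sample_binary_web(pweb, 0)
    assert bweb.n_links == int((pweb.A > 0).sum())  # all-ones: nothing pruned
    deg = bweb.adj.sum(0) + bweb.adj.sum(1)
    assert (deg > 0).all()

    pweb.A[:] = 0.0
    empty = sample_binary_web(pweb, 0)
    assert empty.n_nodes == 0 and empty.n_links == 0


def test_single_edge_inclusion_frequency():
    """Bernoulli sampling of a single A = 0.5 edge: binomial check at 3 SE."""
    nodes = {
        "p1": Node("p1", "plant"),
        "h1": Node("h1", "consumer", "herbivore", "herb", 3.0),
    }
    links = [MetawebLink("p1", "h1", 3)]
    sample = PlotSample("P", "B", 1, 1, plant_cover={"p1": 1.0},
                        consumer_abundance={"h1": 1})
    pweb = build_probabilistic_web(sample, nodes, links, ScalarConfig(0.5, 1))
    assert pweb.A.max() == pytest.approx(0.5)
    rng = np.random.default_rng(123)
    n_draws = 10_000
    hits = sum(sample_binary_web(pweb, rng).n_links for _ in range(n_draws))
    se = np.sqrt(0.25 * n_draws)
    assert abs(hits - 0.5 * n_draws) < 3 * se


def test_expected_edge_count(small_pool, small_design):
    """Mean sampled link count equals the sum of probabilities (3 SE, 1000 draws)."""
    sample = small_design.samples[-1]
    pweb = build_probabilistic_web(
        sample, small_pool.nodes, small_pool.links, ScalarConfig(20, 300)
    )
    expect = pweb.A.sum()
    var = (pweb.A * (1 - pweb.A)).sum()
    assert var > 0  # web must contain genuinely probabilistic links
    rng = np.random.default_rng(99)
    n_draws = 1000
    total = sum(sample_binary_web(pweb, rng).n_links for _ in range(n_draws))
    se = np.sqrt(var * n_draws)
    assert abs(total - expect * n_draws) < 3 * se


def test_consumer_subweb_filters_and_is_idempotent():
    nodes, links, sample = _two_level_model()
    pweb = build_probabilistic_web(sample, nodes, links, ScalarConfig(1e12, 1e12))
    bweb = sample_binary_web(pweb, 1)
    sub = consumer_subweb(bweb)
    assert sub.edges() == [("h1", "c1")]
    # edge count equals consumer->consumer edges of the parent
    cc = sum(1 for r, c in bweb.edges()
             if not bweb.is_basal[bweb.node_ids.index(r)])
    assert sub.n_links == cc
    sub2 = consumer_subweb(sub)
    assert sub2.node_ids == sub.node_ids
    assert np.array_equal(sub2.adj, sub.adj)


def test_subweb_of_basal_only_web_is_empty():
    nodes = {"p1": Node("p1", "plant"), "h1": Node("h1", "consumer", "herbivore", "herb")}
    links = [MetawebLink("p1", "h1", 1)]
    sample = PlotSample("P", "B", 1, 1, plant_cover={"p1": 1.0},
                        consumer_abundance={"h1": 2})
    bweb = sample_binary_web(build_probabilistic_web(sample, nodes, links,
                                                     ScalarConfig(1, 1)), 0)
    sub = consumer_subweb(bweb)
    assert sub.n_nodes == 0


def test_calibration_single_pair(small_community):
    nodes, links, design = small_community
    got = calibrate_scalars(design, nodes, links, candidate_grid=[(3.0, 7.0)],
                            iterations=1, max_samples=8)
    assert (got.alpha, got.beta) == (3.0, 7.0)


def test_generality_monotone_in_scalars(small_community):
    """Median omnivore generality is non-decreasing in alpha = beta."""
    nodes, links, design = small_community
    meds = [
        median_omnivore_generality(design, nodes, links, ScalarConfig(v, v),
                                   iterations=2, global_seed=0, max_samples=8)
        for v in (10, 100, 1000, 10000)
    ]
    assert all(a <= b for a, b in zip(meds, meds[1:]))


def test_diversity_scaled_scalars_endpoints():
    base = ScalarConfig(10.0, 40.0)
    assert diversity_scaled_scalars(base, 60, 0.0).beta == 40.0
    assert diversity_scaled_scalars(base, 1, 0.9).beta == 40.0
    half = diversity_scaled_scalars(base, 60, 0.5)
    assert half.beta == pytest.approx(20.0) and half.alpha == 10.0
    mid = diversity_scaled_scalars(base, 30, 0.5)
    assert 20.0 < mid.beta < 40.0
    with pytest.raises(CommunityValidationError):
        diversity_scaled_scalars(base, 1, 1.5)
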