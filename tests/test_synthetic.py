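"""Synthetic community generator: rules, design shape, determinism."""

import numpy as np
import pytest

from motifweb.community import CommunityValidationError, write_community
from motifweb.synthetic import (
    GeneratorConfig,
    generate_community,
    generate_design,
    generate_pool,
    validate_pool,
)


def test_pool_obeys_generative_rules(small_cfg, small_pool):
    validate_pool(small_pool, small_cfg)


def test_default_pool_obeys_generative_rules():
    cfg = GeneratorConfig(global_seed=1)
    validate_pool(generate_pool(cfg), cfg)


def test_no_predators_means_no_trait_links(small_cfg):
    cfg = GeneratorConfig(
        global_seed=2,
        n_consumers=40,
        guild_fractions={"detritivore": 0.4, "herbivore": 0.6},
        n_plants=small_cfg.n_plants,
        plant_group_counts=small_cfg.plant_group_counts,
    )
    pool = generate_pool(cfg)
    assert all(l.link_type in (1, 2, 3) for l in pool.links)


def test_monophagous_herbivores_have_one_type1_link(small_pool):
    per_consumer: dict[str, list] = {}
    for l in small_pool.links:
        per_consumer.setdefault(l.consumer_id, []).append(l)
    for h, cls in small_pool.herbivore_diet_class.items():
        if cls == "mono":
            assert len(per_consumer[h]) == 1
            assert per_consumer[h][0].link_type == 1


def test_infeasible_predator_window_raises(small_cfg):
    cfg = GeneratorConfig(
        global_seed=3,
        n_consumers=30,
        n_plants=small_cfg.n_plants,
        plant_group_counts=small_cfg.plant_group_counts,
        predator_size_window=(1e6, 2e6),  # no prey can satisfy this
    )
    with pytest.raises(CommunityValidationError, match="infeasible"):
        generate_pool(cfg)


def test_design_shape_and_richness_levels(small_cfg, small_design):
    df = small_design.design_frame()
    assert len(df) == small_cfg.n_plots * small_cfg.n_periods
    assert set(df["sown_richness"]) == set(small_cfg.richness_levels)
    assert df.groupby("plot_id")["block_id"].nunique().max() == 1


def test_realized_richness_bounded_by_sown(small_design):
    for s in small_design.samples:
        assert 1 <= len(s.plant_cover) <= s.sown_richness
        assert sum(s.plant_cover.values()) <= 1.0 + 1e-9


def test_realized_richness_saturates():
    """Mean realised richness at sown 60 lands near one half (ca. 33 species)."""
    cfg = GeneratorConfig(global_seed=4)
    pool = generate_pool(cfg)
    design = generate_design(cfg, pool)
    realized = [len(s.plant_cover) for s in design.samples if s.sown_richness == 60]
    assert 28 <= np.mean(realized) <= 38


def test_consumer_richness_monotone_in_sown_richness():
    """Across replicates, mean consumer richness rises with sown richness and
    the herbivore response is steeper than the predator response."""
    rich_means = {}
    guild_slopes = {"herbivore": [], "predator": [], "omnivore": []}
    for seed in range(3):
        cfg = GeneratorConfig(global_seed=100 + seed, n_consumers=150)
        pool = generate_pool(cfg)
        design = generate_design(cfg, pool)
        guild = {nid: n.guild for nid, n in pool.nodes.items()}
        per_level: dict[int, list[int]] = {}
        per_level_guild: dict[str, dict[int, list[int]]] = {
            g: {} for g in guild_slopes
        }
        for s in design.samples:
            per_level.setdefault(s.sown_richness, []).append(len(s.consumer_abundance))
            for g in guild_slopes:
                per_level_guild[g].setdefault(s.sown_richness, []).append(
                    sum(1 for c in s.consumer_abundance if guild[c] == g)
                )
        for lvl, v in per_level.items():
            rich_means.setdefault(lvl, []).append(np.mean(v))
        for g in guild_slopes:
            lvls = sorted(per_level_guild[g])
            x = np.log2(lvls)
            y = [np.mean(per_level_guild[g][l]) for l in lvls]
            guild_slopes[g].append(np.polyfit(x, y, 1)[0])
    levels = sorted(rich_means)
    means = [np.mean(rich_means[l]) for l in levels]
    assert all(a <= b + 1e-9 for a, b in zip(means, means[1:]))
    assert np.mean(guild_slopes["herbivore"]) > np.mean(guild_slopes["predator"]) > 0
    # omnivores respond more weakly than herbivores: their share declines
    assert np.mean(guild_slopes["omnivore"]) < np.mean(guild_slopes["herbivore"])


def test_generator_is_byte_deterministic(tmp_path, small_cfg):
    a = generate_community(small_cfg)
    b = generate_community(small_cfg)
    pa = write_community(*a, tmp_path / "a")
    pb = write_community(*b, tmp_path / "b")
    for name in pa:
        assert open(pa[name], "rb").read() == open(pb[name], "rb").read()


def test_different_seeds_differ(small_cfg):
    import dataclasses

    other = dataclasses.replace(small_cfg, global_seed=small_cfg.global_seed + 1)
    a = generate_pool(small_cfg)
    b = generate_pool(other)
    assert {(l.resource_id, l.consumer_id) for l in a.links} != {
        (l.resource_id, l.consumer_id) for l in b.links
    }


def test_config_validation():
    with pytest.raises(CommunityValidationError):
        GeneratorConfig(guild_fractions={"herbivore": 0.5})
    with pytest.raises(CommunityValidationError):
        GeneratorConfig(n_plants=10, plant_group_counts=(5, 5, 5, 5))
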