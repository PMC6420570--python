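"""Synthetic grassland communities shaped like a sown-diversity experiment.

The generator emulates the data layout and marginal structure that the
analysis assumes, without imitating any real taxa:

* a plant pool (default 60 species) split into four functional groups
  (grasses, small herbs, tall herbs, legumes) and botanical families;
* six static basal resources (detritus, moss, algae, fungi, dung, carrion)
  present on every plot;
* a consumer pool partitioned into detritivores, herbivores, omnivores and
  predators with guild-specific body sizes and strata;
* a rule-based metaweb: monophagous herbivores get a single type-1 plant
  link, oligophages a type-2 family, generalists a type-3 functional group;
  detritivores feed on static resources; predator links follow a body-size
  window plus stratum compatibility (type 4, or 5 when both rules bind);
  omnivores combine a plant/static side with a predatory side;
* 80 plots x 4 blocks x 4 periods sown with 1, 2, 4, 8, 16 or 60 species;
  realised plant richness is a saturating thinning of the sown set
  (about 33 realised species at sown 60 by default); covers follow a
  geometric rank-abundance series;
* consumer colonisation is logistic in the fraction of the species' metaweb
  diet present locally, with guild-specific baseline and steepness chosen so
  herbivore richness responds to plant richness more strongly than predator
  richness, and the omnivore share declines along the gradient; counts are
  lognormal.

Everything is driven by one global seed and is byte-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .community import (
    CommunityValidationError,
    ExperimentDesign,
    MetawebLink,
    Node,
    PlotSample,
    STATIC_RESOURCES,
)

PLANT_GROUPS = ("grass", "small_herb", "tall_herb", "legume")


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic community generator (units: mm, counts)."""

    global_seed: int = 0
    # species pool
    n_plants: int = 60
    plant_group_counts: tuple[int, int, int, int] = (16, 12, 20, 12)
    n_plant_families: int = 12
    n_consumers: int = 403
    guild_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "detritivore": 0.20, "herbivore": 0.38, "omnivore": 0.12, "predator": 0.30,
        }
    )
    # body length lognormal parameters per guild (meanlog, sdlog of mm)
    body_length_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "detritivore": (1.8, 0.5), "herbivore": (1.4, 0.5),
            "omnivore": (1.8, 0.5), "predator": (1.8, 0.6),
        }
    )
    # herbivore diet breadth
    monophagy_fraction: float = 0.15
    oligophagy_fraction: float = 0.50  # remainder are functional-group generalists
    # predator rules: prey length within [lo, hi] * predator length
    predator_size_window: tuple[float, float] = (0.15, 1.2)
    omnivore_size_window: tuple[float, float] = (0.2, 1.0)
    omnivore_plant_prob: float = 0.7
    omnivore_static_prob: float = 0.3
    # colonisation: presence prob = sigmoid(b0 + k * diet_fraction_present)
    colonization: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "detritivore": (-0.8, 0.0), "herbivore": (-4.8, 6.0),
            "omnivore": (-0.8, 1.2), "predator": (-3.8, 4.2),
        }
    )
    # abundances and covers
    abundance_meanlog: float = 2.0
    abundance_sdlog: float = 1.2
    cover_total: float = 0.8
    cover_decay: float = 0.1  # geometric rank-abundance decay
    # design
    richness_levels: tuple[int, ...] = (1, 2, 4, 8, 16, 60)
    plots_per_level_per_block: tuple[int, ...] = (4, 4, 4, 4, 3, 1)
    n_blocks: int = 4
    n_periods: int = 4
    thinning_rate: float = 0.01386  # survival = 1 / (1 + rate * (sown - 1))

    def __post_init__(self) -> None:
        if abs(sum(self.guild_fractions.values()) - 1.0) > 1e-9:
            raise CommunityValidationError("guild fractions must sum to 1")
        if sum(self.plant_group_counts) != self.n_plants:
            raise CommunityValidationError("plant group counts must sum to n_plants")
        if self.monophagy_fraction + self.oligophagy_fraction > 1.0 + 1e-9:
            raise CommunityValidationError("herbivore diet fractions exceed 1")

    @property
    def plots_per_block(self) -> int:
        return sum(self.plots_per_level_per_block)

    @property
    def n_plots(self) -> int:
        return self.n_blocks * self.plots_per_block


@dataclass
class SpeciesPool:
    """Output of :func:`generate_pool`: nodes, metaweb, and plant taxonomy."""

    nodes: dict[str, Node]
    links: list[MetawebLink]
    plant_group: dict[str, str]
    plant_family: dict[str, str]
    herbivore_diet_class: dict[str, str]  # mono / oligo / generalist


_STRATUM_MIX = {
    "detritivore": (("ground", 0.8), ("both", 0.2)),
    "herbivore": (("herb", 0.7), ("ground", 0.15), ("both", 0.15)),
    "omnivore": (("ground", 0.4), ("herb", 0.3), ("both", 0.3)),
    "predator": (("ground", 0.4), ("herb", 0.4), ("both", 0.2)),
}


def _strata_compatible(pred: str, prey: str) -> bool:
    return pred == "both" or prey == "both" or pred == prey


def _guild_counts(cfg: GeneratorConfig) -> dict[str, int]:
    guilds = sorted(cfg.guild_fractions)
    counts = {g: int(round(cfg.guild_fractions[g] * cfg.n_consumers)) for g in guilds}
    # fix rounding drift on the largest guild
    drift = cfg.n_consumers - sum(counts.values())
    counts[max(counts, key=counts.get)] += drift
    return counts


def generate_pool(cfg: GeneratorConfig) -> SpeciesPool:
    """Draw the species pool and its rule-based metaweb."""
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.global_seed), 101]))
    nodes: dict[str, Node] = {}
    plant_group: dict[str, str] = {}
    plant_family: dict[str, str] = {}

    fams_per_group = max(1, cfg.n_plant_families // len(PLANT_GROUPS))
    pid = 0
    for group, count in zip(PLANT_GROUPS, cfg.plant_group_counts):
        for k in range(count):
            pid += 1
            nid = f"p{pid:03d}"
            nodes[nid] = Node(nid, "plant")
            plant_group[nid] = group
            plant_family[nid] = f"{group}_fam{k % fams_per_group}"

    for s in STATIC_RESOURCES:
        nodes[s] = Node(s, "static_resource")

    counts = _guild_counts(cfg)
    consumers: dict[str, list[str]] = {
        g: [] for g in ("detritivore", "herbivore", "omnivore", "predator")
    }
    consumers.update({g: [] for g in counts})
    cid = 0
    for guild in sorted(counts):
        meanlog, sdlog = cfg.body_length_params[guild]
        mix_names = [s for s, _ in _STRATUM_MIX[guild]]
        mix_probs = [p for _, p in _STRATUM_MIX[guild]]
        for _ in range(counts[guild]):
            cid += 1
            nid = f"c{cid:03d}"
            stratum = str(rng.choice(mix_names, p=mix_probs))
            length = float(rng.lognormal(meanlog, sdlog))
            nodes[nid] = Node(nid, "consumer", guild, stratum, round(length, 3))
            consumers[guild].append(nid)

    plants = sorted(plant_group)
    by_family: dict[str, list[str]] = {}
    by_group: dict[str, list[str]] = {}
    for p in plants:
        by_family.setdefault(plant_family[p], []).append(p)
        by_group.setdefault(plant_group[p], []).append(p)

    links: list[MetawebLink] = []
    diet_class: dict[str, str] = {}

    def _predatory_links(pred_id: str, window: tuple[float, float], prey_pool: list[str]):
        pred = nodes[pred_id]
        lo, hi = window
        out = []
        for prey_id in prey_pool:
            if prey_id == pred_id:
                continue
            prey = nodes[prey_id]
            if not _strata_compatible(pred.stratum, prey.stratum):
                continue
            if lo * pred.body_length <= prey.body_length <= hi * pred.body_length:
                ltype = 4 if pred.stratum == "both" else 5
                out.append(MetawebLink(prey_id, pred_id, ltype))
        return out

    all_consumer_ids = sorted(nid for n in consumers.values() for nid in n)

    for h in consumers["herbivore"]:
        u = rng.random()
        if u < cfg.monophagy_fraction:
            diet_class[h] = "mono"
            links.append(MetawebLink(str(rng.choice(plants)), h, 1))
        elif u < cfg.monophagy_fraction + cfg.oligophagy_fraction:
            diet_class[h] = "oligo"
            fam = str(rng.choice(sorted(by_family)))
            links.extend(MetawebLink(p, h, 2) for p in by_family[fam])
        else:
            diet_class[h] = "generalist"
            grp = str(rng.choice(PLANT_GROUPS))
            links.extend(MetawebLink(p, h, 3) for p in by_group[grp])

    for d in consumers["detritivore"]:
        k = int(rng.integers(2, 5))
        picks = sorted(rng.choice(STATIC_RESOURCES, size=k, replace=False).tolist())
        ltype = 2 if k == 2 else 3
        links.extend(MetawebLink(s, d, ltype) for s in picks)

    for o in consumers["omnivore"]:
        if rng.random() < cfg.omnivore_plant_prob:
            grp = str(rng.choice(PLANT_GROUPS))
            links.extend(MetawebLink(p, o, 3) for p in by_group[grp])
        if rng.random() < cfg.omnivore_static_prob:
            picks = sorted(rng.choice(STATIC_RESOURCES, size=2, replace=False).tolist())
            links.extend(MetawebLink(s, o, 3) for s in picks)
        links.extend(_predatory_links(o, cfg.omnivore_size_window, all_consumer_ids))

    any_prey = False
    for p in consumers["predator"]:
        plinks = _predatory_links(p, cfg.predator_size_window, all_consumer_ids)
        any_prey = any_prey or bool(plinks)
        links.extend(plinks)
    if consumers["predator"] and not any_prey:
        raise CommunityValidationError(
            "infeasible config: the predator size window excludes all prey"
        )

    # deduplicate (an omnivore may be reachable twice) and canonicalise order
    uniq = {(l.resource_id, l.consumer_id): l for l in links}
    links = [uniq[k] for k in sorted(uniq)]
    return SpeciesPool(nodes, links, plant_group, plant_family, diet_class)


def validate_pool(pool: SpeciesPool, cfg: GeneratorConfig) -> None:
    """Independently re-check every metaweb link against the generative rules."""
    nodes = pool.nodes
    for lk in pool.links:
        res, cons = nodes[lk.resource_id], nodes[lk.consumer_id]
        if cons.role != "consumer" or res.role == "consumer" and cons.guild == "herbivore":
            raise CommunityValidationError(f"rule violation at {lk}")
        if cons.guild == "herbivore" and res.role != "plant":
            raise CommunityValidationError(f"herbivore {cons.id} eats non-plant {res.id}")
        if cons.guild == "detritivore" and res.role != "static_resource":
            raise CommunityValidationError(f"detritivore {cons.id} eats non-static {res.id}")
        if lk.link_type in (4, 5):
            if res.role != "consumer":
                raise CommunityValidationError(f"type-{lk.link_type} link with basal resource")
            window = (
                cfg.omnivore_size_window if cons.guild == "omnivore" else cfg.predator_size_window
            )
            ratio = res.body_length / cons.body_length
            if not (window[0] - 1e-9 <= ratio <= window[1] + 1e-9):
                raise CommunityValidationError(f"size window violated: {lk}")
            if not _strata_compatible(cons.stratum, res.stratum):
                raise CommunityValidationError(f"stratum rule violated: {lk}")
    for h, dc in pool.herbivore_diet_class.items():
        n_links = sum(1 for l in pool.links if l.consumer_id == h)
        if dc == "mono" and n_links != 1:
            raise CommunityValidationError(f"monophage {h} has {n_links} links")


def _survival(sown: int, rate: float) -> float:
    return 1.0 / (1.0 + rate * (sown - 1))


def generate_design(cfg: GeneratorConfig, pool: SpeciesPool) -> ExperimentDesign:
    """Draw the plot layout, realised plant communities and consumer samples."""
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.global_seed), 202]))
    nodes = pool.nodes
    plants = sorted(pool.plant_group)
    statics = frozenset(s for s in nodes if nodes[s].role == "static_resource")
    consumer_ids = sorted(n for n in nodes if nodes[n].role == "consumer")
    diet = {c: [] for c in consumer_ids}
    for lk in pool.links:
        diet[lk.consumer_id].append(lk.resource_id)

    stage1 = [c for c in consumer_ids if nodes[c].guild in ("detritivore", "herbivore")]
    stage2a = [c for c in consumer_ids if nodes[c].guild == "omnivore"]
    stage2b = [c for c in consumer_ids if nodes[c].guild == "predator"]

    samples: list[PlotSample] = []
    plot_no = 0
    for b in range(1, cfg.n_blocks + 1):
        block = f"B{b}"
        for level, n_level in zip(cfg.richness_levels, cfg.plots_per_level_per_block):
            for _ in range(n_level):
                plot_no += 1
                plot = f"{block}P{plot_no:03d}"
                sown = sorted(rng.choice(plants, size=level, replace=False).tolist())
                for period in range(1, cfg.n_periods + 1):
                    samples.append(
                        _sample_plot_period(
                            cfg, pool, rng, plot, block, period, level, sown,
                            statics, diet, stage1, stage2a, stage2b,
                        )
                    )
    design = ExperimentDesign(samples)
    design.validate(nodes)
    return design


def _sample_plot_period(
    cfg, pool, rng, plot, block, period, level, sown, statics, diet,
    stage1, stage2a, stage2b,
) -> PlotSample:
    nodes = pool.nodes
    surv = _survival(level, cfg.thinning_rate)
    realized = [p for p in sown if rng.random() < surv]
    if not realized:
        realized = [sown[int(rng.integers(len(sown)))]]
    ranks = rng.permutation(len(realized))
    weights = (1.0 - cfg.cover_decay) ** ranks
    covers = cfg.cover_total * weights / weights.sum()
    plant_cover = {p: float(c) for p, c in zip(realized, covers)}

    present: set[str] = set(realized) | set(statics)
    abundance: dict[str, float] = {}

    def _colonize(candidates: list[str]) -> None:
        for c in candidates:
            d = diet[c]
            if not d:
                continue
            f = sum(1 for r in d if r in present) / len(d)
            if f == 0:
                continue
            b0, k = cfg.colonization[nodes[c].guild]
            if rng.random() < _sigmoid(b0 + k * f):
                present.add(c)
                abundance[c] = float(
                    math.ceil(rng.lognormal(cfg.abundance_meanlog, cfg.abundance_sdlog))
                )

    _colonize(stage1)
    _colonize(stage2a)
    _colonize(stage2b)

    return PlotSample(
        plot_id=plot,
        block_id=block,
        time_period=period,
        sown_richness=level,
        plant_cover=plant_cover,
        consumer_abundance=abundance,
        static_resources=statics,
    )


def generate_community(
    cfg: GeneratorConfig,
) -> tuple[dict[str, Node], list[MetawebLink], ExperimentDesign]:
    """Pool + design in one call, in the shape :func:`read_community` returns."""
    pool = generate_pool(cfg)
    design = generate_design(cfg, pool)
    return pool.nodes, pool.links, design
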