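"""Core domain model: species nodes, metaweb links, plot samples and table IO.

The community model mirrors how grassland biodiversity experiments organise
their data: a species-trait table (one row per node, including non-living
basal resources such as detritus), a global metaweb of plausible feeding
links, per-plot/per-period abundance records, and an experiment-design table
tying plots to blocks and sown plant richness.

All tables are UTF-8, tab-separated, single header row.  Identifiers are
opaque strings so that synthetic and field data share one schema.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd

ROLES = ("plant", "static_resource", "consumer")
GUILDS = ("none", "detritivore", "herbivore", "omnivore", "predator")
STRATA = ("ground", "herb", "both", "none")

#: the six ubiquitous non-plant basal resources assumed present on every plot
STATIC_RESOURCES = ("detritus", "moss", "algae", "fungi", "dung", "carrion")


class CommunityValidationError(ValueError):
    """Raised when tables or in-memory objects violate the community schema."""


@dataclass(frozen=True)
class Node:
    """A species or static basal resource.

    Parameters
    ----------
    id : str
        Opaque unique identifier.
    role : {'plant', 'static_resource', 'consumer'}
    guild : {'none', 'detritivore', 'herbivore', 'omnivore', 'predator'}
        ``none`` for basal nodes (plants and static resources).
    stratum : {'ground', 'herb', 'both', 'none'}
        Vertical habitat stratum; ``none`` only for basal nodes.
    body_length : float or None
        Body length in mm (consumers only, optional).
    """

    id: str
    role: str
    guild: str = "none"
    stratum: str = "none"
    body_length: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise CommunityValidationError(f"unknown role {self.role!r} for node {self.id!r}")
        if self.guild not in GUILDS:
            raise CommunityValidationError(f"unknown guild {self.guild!r} for node {self.id!r}")
        if self.stratum not in STRATA:
            raise CommunityValidationError(f"unknown stratum {self.stratum!r} for node {self.id!r}")
        if self.role in ("plant", "static_resource"):
            if self.guild != "none":
                raise CommunityValidationError(
                    f"basal node {self.id!r} must have guild 'none', got {self.guild!r}"
                )
        else:
            if self.guild == "none":
                raise CommunityValidationError(f"consumer {self.id!r} must have a feeding guild")
            if self.stratum == "none":
                raise CommunityValidationError(f"consumer {self.id!r} must have a stratum")
        if self.body_length is not None and not self.body_length > 0:
            raise CommunityValidationError(f"body_length of {self.id!r} must be positive")

    @property
    def is_basal(self) -> bool:
        return self.role in ("plant", "static_resource")


@dataclass(frozen=True)
class MetawebLink:
    """A directed plausible feeding link, resource -> consumer.

    ``link_type`` follows the five-way evidence scheme used for trophic
    metawebs: 1 specific literature record, 2 generalised literature record,
    3 trophic-guild rule, 4 trait-based rule, 5 combined trait-based rules.
    """

    resource_id: str
    consumer_id: str
    link_type: int

    def __post_init__(self) -> None:
        if self.link_type not in (1, 2, 3, 4, 5):
            raise CommunityValidationError(
                f"link_type must be in 1..5, got {self.link_type!r} "
                f"({self.resource_id}->{self.consumer_id})"
            )
        if self.resource_id == self.consumer_id:
            raise CommunityValidationError(
                f"self-link (cannibalism) not allowed: {self.resource_id!r}"
            )


@dataclass
class PlotSample:
    """Observed community of one plot in one time period."""

    plot_id: str
    block_id: str
    time_period: int
    sown_richness: int
    plant_cover: dict[str, float] = field(default_factory=dict)
    consumer_abundance: dict[str, float] = field(default_factory=dict)
    static_resources: frozenset[str] = frozenset()

    def validate(self, nodes: dict[str, Node]) -> None:
        total = sum(self.plant_cover.values())
        if total > 1.0 + 1e-9:
            raise CommunityValidationError(
                f"plant cover on {self.plot_id}/{self.time_period} sums to {total:.4f} > 1"
            )
        for nid, cov in self.plant_cover.items():
            node = _resolve(nodes, nid)
            if node.role != "plant":
                raise CommunityValidationError(f"cover value keyed by non-plant {nid!r}")
            if cov < 0:
                raise CommunityValidationError(f"negative cover for {nid!r}")
        for nid, cnt in self.consumer_abundance.items():
            node = _resolve(nodes, nid)
            if node.role != "consumer":
                raise CommunityValidationError(f"count value keyed by non-consumer {nid!r}")
            if cnt < 0:
                raise CommunityValidationError(f"negative abundance for {nid!r}")
        for nid in self.static_resources:
            if _resolve(nodes, nid).role != "static_resource":
                raise CommunityValidationError(f"{nid!r} listed as static resource but is not")


@dataclass
class ExperimentDesign:
    """All plot samples of one experiment (plots x periods, in blocks)."""

    samples: list[PlotSample]

    @property
    def plot_ids(self) -> list[str]:
        return sorted({s.plot_id for s in self.samples})

    @property
    def periods(self) -> list[int]:
        return sorted({s.time_period for s in self.samples})

    @property
    def blocks(self) -> list[str]:
        return sorted({s.block_id for s in self.samples})

    def validate(self, nodes: dict[str, Node]) -> None:
        plot_block: dict[str, str] = {}
        plot_rich: dict[str, int] = {}
        seen: set[tuple[str, int]] = set()
        for s in self.samples:
            key = (s.plot_id, s.time_period)
            if key in seen:
                raise CommunityValidationError(f"duplicate sample for {key}")
            seen.add(key)
            if plot_block.setdefault(s.plot_id, s.block_id) != s.block_id:
                raise CommunityValidationError(f"plot {s.plot_id!r} assigned to two blocks")
            if plot_rich.setdefault(s.plot_id, s.sown_richness) != s.sown_richness:
                raise CommunityValidationError(f"plot {s.plot_id!r} has two sown richness values")
            s.validate(nodes)

    def design_frame(self) -> pd.DataFrame:
        """Per-sample design covariates (one row per plot-period)."""
        rows = [
            {
                "plot_id": s.plot_id,
                "block_id": s.block_id,
                "time_period": s.time_period,
                "sown_richness": s.sown_richness,
            }
            for s in self.samples
        ]
        return pd.DataFrame(rows).sort_values(["plot_id", "time_period"], ignore_index=True)


def _resolve(nodes: dict[str, Node], nid: str) -> Node:
    try:
        return nodes[nid]
    except KeyError:
        raise CommunityValidationError(f"id {nid!r} referenced but not declared in traits") from None


def validate_metaweb(nodes: dict[str, Node], links: list[MetawebLink]) -> None:
    """Check role constraints and uniqueness of a metaweb against a node set."""
    seen: set[tuple[str, str]] = set()
    for lk in links:
        res = _resolve(nodes, lk.resource_id)
        cons = _resolve(nodes, lk.consumer_id)
        if cons.role != "consumer":
            raise CommunityValidationError(
                f"{lk.consumer_id!r} ({cons.role}) cannot be a consumer in the metaweb"
            )
        if res.role == "consumer" and lk.link_type in (2, 3) and cons.guild == "herbivore":
            # herbivores feed on basal resources only under the guild rules;
            # tolerated for omnivores/predators/detritivores
            pass
        key = (lk.resource_id, lk.consumer_id)
        if key in seen:
            raise CommunityValidationError(f"duplicate metaweb link {key}")
        seen.add(key)


# ---------------------------------------------------------------------------
# Table IO

TRAIT_COLS = ["id", "role", "guild", "stratum", "body_length_mm"]
METAWEB_COLS = ["resource_id", "consumer_id", "link_type"]
ABUNDANCE_COLS = ["plot_id", "time_period", "node_id", "value", "value_kind"]
DESIGN_COLS = ["plot_id", "block_id", "sown_richness"]


def _read_tsv(path: str | os.PathLike, cols: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise CommunityValidationError(f"{path}: missing columns {missing}")
    return df


def read_community(
    trait_path: str | os.PathLike,
    abundance_path: str | os.PathLike,
    metaweb_path: str | os.PathLike,
    design_path: str | os.PathLike,
) -> tuple[dict[str, Node], list[MetawebLink], ExperimentDesign]:
    """Read the four community tables into a cross-referenced model.

    Returns ``(nodes, metaweb_links, design)``.  Static resources are assumed
    present on every plot, so they carry no abundance rows; every node with
    role ``static_resource`` is attached to each plot sample.
    """
    traits = _read_tsv(trait_path, TRAIT_COLS)
    nodes: dict[str, Node] = {}
    for row in traits.itertuples(index=False):
        if row.id in nodes:
            raise CommunityValidationError(f"duplicate node id {row.id!r}")
        bl = float(row.body_length_mm) if row.body_length_mm not in ("", "NA") else None
        nodes[row.id] = Node(row.id, row.role, row.guild, row.stratum, bl)

    mw = _read_tsv(metaweb_path, METAWEB_COLS)
    links = [
        MetawebLink(r.resource_id, r.consumer_id, int(r.link_type))
        for r in mw.itertuples(index=False)
    ]
    validate_metaweb(nodes, links)

    design_df = _read_tsv(design_path, DESIGN_COLS)
    plot_meta: dict[str, tuple[str, int]] = {}
    for r in design_df.itertuples(index=False):
        if r.plot_id in plot_meta:
            raise CommunityValidationError(f"duplicate design row for plot {r.plot_id!r}")
        plot_meta[r.plot_id] = (r.block_id, int(r.sown_richness))

    ab = _read_tsv(abundance_path, ABUNDANCE_COLS)
    statics = frozenset(nid for nid, n in nodes.items() if n.role == "static_resource")
    samples: dict[tuple[str, int], PlotSample] = {}
    for r in ab.itertuples(index=False):
        if r.plot_id not in plot_meta:
            raise CommunityValidationError(f"abundance row for undeclared plot {r.plot_id!r}")
        block, rich = plot_meta[r.plot_id]
        key = (r.plot_id, int(r.time_period))
        sample = samples.get(key)
        if sample is None:
            sample = samples[key] = PlotSample(
                plot_id=r.plot_id,
                block_id=block,
                time_period=int(r.time_period),
                sown_richness=rich,
                static_resources=statics,
            )
        value = float(r.value)
        if r.value_kind == "cover":
            sample.plant_cover[r.node_id] = value
        elif r.value_kind == "count":
            sample.consumer_abundance[r.node_id] = value
        else:
            raise CommunityValidationError(f"unknown value_kind {r.value_kind!r}")

    design = ExperimentDesign(sorted(samples.values(), key=lambda s: (s.plot_id, s.time_period)))
    design.validate(nodes)
    return nodes, links, design


def _fmt(x: float) -> str:
    return format(float(x), ".10g")


def write_community(
    nodes: dict[str, Node],
    links: list[MetawebLink],
    design: ExperimentDesign,
    out_dir: str | os.PathLike,
) -> dict[str, str]:
    """Write the four community tables in canonical (sorted) order.

    Returns a mapping of table name to file path.  ``read_community`` on the
    output reproduces the model; a second write is byte-identical.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {name: os.path.join(out_dir, f"{name}.tsv")
             for name in ("traits", "metaweb", "abundance", "design")}

    trait_rows = [
        {
            "id": n.id,
            "role": n.role,
            "guild": n.guild,
            "stratum": n.stratum,
            "body_length_mm": "" if n.body_length is None else _fmt(n.body_length),
        }
        for n in sorted(nodes.values(), key=lambda n: n.id)
    ]
    pd.DataFrame(trait_rows, columns=TRAIT_COLS).to_csv(paths["traits"], sep="\t", index=False)

    link_rows = [
        {"resource_id": l.resource_id, "consumer_id": l.consumer_id, "link_type": l.link_type}
        for l in sorted(links, key=lambda l: (l.resource_id, l.consumer_id))
    ]
    pd.DataFrame(link_rows, columns=METAWEB_COLS).to_csv(paths["metaweb"], sep="\t", index=False)

    ab_rows = []
    for s in sorted(design.samples, key=lambda s: (s.plot_id, s.time_period)):
        for nid in sorted(s.plant_cover):
            ab_rows.append((s.plot_id, s.time_period, nid, _fmt(s.plant_cover[nid]), "cover"))
        for nid in sorted(s.consumer_abundance):
            ab_rows.append((s.plot_id, s.time_period, nid, _fmt(s.consumer_abundance[nid]), "count"))
    pd.DataFrame(ab_rows, columns=ABUNDANCE_COLS).to_csv(paths["abundance"], sep="\t", index=False)

    seen_plots: set[str] = set()
    d_rows = []
    for s in sorted(design.samples, key=lambda s: (s.plot_id, s.time_period)):
        if s.plot_id not in seen_plots:
            seen_plots.add(s.plot_id)
            d_rows.append((s.plot_id, s.block_id, s.sown_richness))
    pd.DataFrame(d_rows, columns=DESIGN_COLS).to_csv(paths["design"], sep="\t", index=False)

    return paths
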