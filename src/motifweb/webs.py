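"""Plot-level probabilistic food webs and their binary realisations.

A plot-period food web starts from the metaweb restricted to the locally
co-occurring nodes.  Each supported link (i eaten by j) gets an interaction
probability ``A_ij = N(i, j) * T(i, j)`` where T is 1 on the metaweb support
and the encounter probability N depends on the evidence type of the link and
the role of the resource:

* link type 1 (specific literature record): N = 1 — specialists find their
  resource whenever both occur.
* link types 2-3 with a consumer or static resource as the resource: N = 1 —
  generalised records on ubiquitous or mobile resources.
* link types 2-3 with a plant resource: N = min(1, alpha * n_i * n_j).
* link types 4-5 (trait-based predator-prey rules): N = min(1, beta * n_i * n_j).

``n`` is relative cover for plants (renormalised over the plants present on
the plot-period) and within-stratum relative abundance for consumers.  The
products are clipped at 1 so A stays a probability.  Binary webs are drawn by
independent Bernoulli sampling of A; nodes left with degree 0 are dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .community import CommunityValidationError, MetawebLink, Node, PlotSample


@dataclass(frozen=True)
class ScalarConfig:
    """Encounter-probability scalars.

    alpha scales plant-consumer encounters (link types 2-3 with a plant
    resource), beta scales predator-prey encounters (link types 4-5).  Both
    are dimensionless and must be positive; larger values make the generalist
    part of the web denser.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise CommunityValidationError("alpha and beta must be positive")


def encounter_probability(
    link_type: int,
    resource_role: str,
    n_resource: float,
    n_consumer: float,
    scalars: ScalarConfig,
) -> float:
    """Encounter probability N for one potential link (see module docstring)."""
    if link_type == 1:
        return 1.0
    if link_type in (2, 3):
        if resource_role in ("consumer", "static_resource"):
            return 1.0
        return min(1.0, scalars.alpha * n_resource * n_consumer)
    if link_type in (4, 5):
        return min(1.0, scalars.beta * n_resource * n_consumer)
    raise CommunityValidationError(f"unknown link type {link_type!r}")


def interaction_probability(
    link: MetawebLink,
    resource_node: Node,
    consumer_node: Node,
    n_resource: float,
    n_consumer: float,
    scalars: ScalarConfig,
) -> float:
    """Interaction probability A_ij for a metaweb-supported link (T = 1)."""
    if link.resource_id != resource_node.id or link.consumer_id != consumer_node.id:
        raise CommunityValidationError("link endpoints do not match the given nodes")
    return encounter_probability(
        link.link_type, resource_node.role, n_resource, n_consumer, scalars
    )


@dataclass
class ProbabilisticWeb:
    """Matrix of interaction probabilities for one plot-period.

    ``A[i, j]`` is the probability that node i is eaten by node j among the
    co-occurring nodes (basal resources first is not guaranteed; use
    ``is_basal``).  The support of A is contained in the metaweb.
    """

    plot_id: str
    time_period: int
    node_ids: list[str]
    is_basal: np.ndarray
    guilds: list[str]
    A: np.ndarray
    rel_abundance: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)


@dataclass
class BinaryWeb:
    """One sampled binary food web (edges point resource -> consumer)."""

    plot_id: str
    time_period: int
    iteration: int
    node_ids: list[str]
    is_basal: np.ndarray
    guilds: list[str]
    adj: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_links(self) -> int:
        return int(self.adj.sum())

    def edges(self) -> list[tuple[str, str]]:
        rs, cs = np.nonzero(self.adj)
        return [(self.node_ids[r], self.node_ids[c]) for r, c in zip(rs, cs)]

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for nid, basal, guild in zip(self.node_ids, self.is_basal, self.guilds):
            g.add_node(nid, basal=bool(basal), guild=guild)
        g.add_edges_from(self.edges())
        return g


def _consumer_rel_abundance(
    counts: dict[str, float], nodes: dict[str, Node]
) -> dict[str, float]:
    """Within-stratum relative abundances; 'both'-stratum species enter both
    stratum totals and receive the mean of their two shares."""
    ground_tot = sum(
        c for nid, c in counts.items() if nodes[nid].stratum in ("ground", "both")
    )
    herb_tot = sum(
        c for nid, c in counts.items() if nodes[nid].stratum in ("herb", "both")
    )
    rel: dict[str, float] = {}
    for nid, c in counts.items():
        st = nodes[nid].stratum
        if st == "ground":
            rel[nid] = c / ground_tot if ground_tot > 0 else 0.0
        elif st == "herb":
            rel[nid] = c / herb_tot if herb_tot > 0 else 0.0
        else:  # both
            g = c / ground_tot if ground_tot > 0 else 0.0
            h = c / herb_tot if herb_tot > 0 else 0.0
            rel[nid] = 0.5 * (g + h)
    return rel


def build_probabilistic_web(
    plot_sample: PlotSample,
    nodes: dict[str, Node],
    metaweb: list[MetawebLink],
    scalars: ScalarConfig,
) -> ProbabilisticWeb:
    """Restrict the metaweb to a plot-period and attach probabilities.

    Co-occurring nodes are the plants with nonzero cover, the consumers with
    nonzero counts, and every static resource (assumed ubiquitous).
    """
    plants = sorted(nid for nid, cov in plot_sample.plant_cover.items() if cov > 0)
    consumers = sorted(nid for nid, c in plot_sample.consumer_abundance.items() if c > 0)
    statics = sorted(plot_sample.static_resources)
    if not plants and not consumers:
        raise CommunityValidationError(
            f"degenerate plot {plot_sample.plot_id}/{plot_sample.time_period}: "
            "no plants and no consumers"
        )
    node_ids = plants + statics + consumers
    index = {nid: k for k, nid in enumerate(node_ids)}

    cover_tot = sum(plot_sample.plant_cover[p] for p in plants)
    n_val = {p: plot_sample.plant_cover[p] / cover_tot for p in plants}
    n_val.update({s: 1.0 for s in statics})
    n_val.update(
        _consumer_rel_abundance(
            {c: plot_sample.consumer_abundance[c] for c in consumers}, nodes
        )
    )

    n = len(node_ids)
    A = np.zeros((n, n), dtype=np.float64)
    for link in metaweb:
        i = index.get(link.resource_id)
        j = index.get(link.consumer_id)
        if i is None or j is None:
            continue
        A[i, j] = encounter_probability(
            link.link_type,
            nodes[link.resource_id].role,
            n_val[link.resource_id],
            n_val[link.consumer_id],
            scalars,
        )
    np.fill_diagonal(A, 0.0)

    is_basal = np.array([nodes[nid].is_basal for nid in node_ids], dtype=bool)
    guilds = [nodes[nid].guild for nid in node_ids]
    rel = np.array([n_val[nid] for nid in node_ids], dtype=np.float64)
    return ProbabilisticWeb(
        plot_id=plot_sample.plot_id,
        time_period=plot_sample.time_period,
        node_ids=node_ids,
        is_basal=is_basal,
        guilds=guilds,
        A=A,
        rel_abundance=rel,
    )


def _prune(adj: np.ndarray, keep_info: tuple) -> tuple[np.ndarray, list[int]]:
    deg = adj.sum(axis=0) + adj.sum(axis=1)
    keep = np.nonzero(deg > 0)[0]
    return adj[np.ix_(keep, keep)], list(keep)


def sample_binary_web(
    pweb: ProbabilisticWeb, rng: np.random.Generator | int, iteration: int = 0
) -> BinaryWeb:
    """Draw one binary web: Bernoulli(A_ij) per potential link, then drop
    degree-0 nodes."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    draws = rng.random(pweb.A.shape)
    adj = (draws < pweb.A).astype(np.uint8)
    sub, keep = _prune(adj, ())
    return BinaryWeb(
        plot_id=pweb.plot_id,
        time_period=pweb.time_period,
        iteration=iteration,
        node_ids=[pweb.node_ids[k] for k in keep],
        is_basal=pweb.is_basal[keep],
        guilds=[pweb.guilds[k] for k in keep],
        adj=np.ascontiguousarray(sub),
    )


def consumer_subweb(bweb: BinaryWeb) -> BinaryWeb:
    """Drop basal nodes (plants and static resources) and then any consumer
    left with degree 0; only consumer-consumer links remain."""
    keep0 = np.nonzero(~bweb.is_basal)[0]
    sub = bweb.adj[np.ix_(keep0, keep0)]
    sub2, keep1 = _prune(sub, ())
    keep = [int(keep0[k]) for k in keep1]
    return BinaryWeb(
        plot_id=bweb.plot_id,
        time_period=bweb.time_period,
        iteration=bweb.iteration,
        node_ids=[bweb.node_ids[k] for k in keep],
        is_basal=bweb.is_basal[keep],
        guilds=[bweb.guilds[k] for k in keep],
        adj=np.ascontiguousarray(sub2),
    )


def iteration_seed(global_seed: int, plot_id: str, period: int, iteration: int) -> int:
    """Deterministic per-iteration seed below 2**31."""
    h = np.random.SeedSequence(
        [int(global_seed), _stable_hash(plot_id), int(period), int(iteration)]
    )
    return int(h.generate_state(1, np.uint32)[0] % (2**31 - 1))


def _stable_hash(s: str) -> int:
    h = 2166136261
    for ch in s.encode():
        h = (h ^ ch) * 16777619 % (2**31)
    return h


def omnivore_generality(bweb: BinaryWeb) -> np.ndarray:
    """Number of resource taxa of each omnivore present in a sampled web."""
    idx = [k for k, g in enumerate(bweb.guilds) if g == "omnivore"]
    if not idx:
        return np.zeros(0)
    return bweb.adj[:, idx].sum(axis=0).astype(float)


def median_omnivore_generality(
    design,
    nodes: dict[str, Node],
    metaweb: list[MetawebLink],
    scalars: ScalarConfig,
    iterations: int = 3,
    global_seed: int = 0,
    max_samples: int | None = 32,
) -> float:
    """Median generality of omnivores pooled over sampled plot-period webs."""
    samples = design.samples
    if max_samples is not None and len(samples) > max_samples:
        step = len(samples) / max_samples
        samples = [samples[int(k * step)] for k in range(max_samples)]
    gens: list[np.ndarray] = []
    for s in samples:
        try:
            pweb = build_probabilistic_web(s, nodes, metaweb, scalars)
        except CommunityValidationError:
            continue
        for it in range(iterations):
            seed = iteration_seed(global_seed, s.plot_id, s.time_period, it)
            bweb = sample_binary_web(pweb, seed, iteration=it)
            g = omnivore_generality(bweb)
            if g.size:
                gens.append(g)
    if not gens:
        raise CommunityValidationError("no omnivores occur in any sampled web")
    return float(np.median(np.concatenate(gens)))


def calibrate_scalars(
    design,
    nodes: dict[str, Node],
    metaweb: list[MetawebLink],
    target_generality: float = 30.0,
    candidate_grid: list[tuple[float, float]] | None = None,
    iterations: int = 3,
    global_seed: int = 0,
    max_samples: int | None = 32,
) -> ScalarConfig:
    """Pick the (alpha, beta) grid point whose median omnivore generality is
    closest to ``target_generality`` (ties: smaller alpha, then smaller beta).

    The default target of 30 resource taxa reflects gut-content evidence that
    omnivore diets expand strongly with plant diversity.
    """
    if candidate_grid is None:
        candidate_grid = [(a, b) for a in (1e1, 1e2, 1e3, 1e4) for b in (1e1, 1e2, 1e3, 1e4)]
    if not candidate_grid:
        raise CommunityValidationError("candidate grid must be nonempty")
    best: tuple[float, float, float] | None = None
    best_pair: tuple[float, float] | None = None
    for alpha, beta in candidate_grid:
        med = median_omnivore_generality(
            design,
            nodes,
            metaweb,
            ScalarConfig(alpha, beta),
            iterations=iterations,
            global_seed=global_seed,
            max_samples=max_samples,
        )
        key = (abs(med - target_generality), alpha, beta)
        if best is None or key < best:
            best = key
            best_pair = (alpha, beta)
    assert best_pair is not None
    return ScalarConfig(*best_pair)


def diversity_scaled_scalars(
    base: ScalarConfig,
    sown_richness: int,
    scenario_strength: float = 0.0,
    richness_range: tuple[int, int] = (1, 60),
) -> ScalarConfig:
    """Scenario variant: weaken predator-prey encounters at high diversity.

    beta decreases linearly from ``base.beta`` at the lowest richness to
    ``(1 - scenario_strength) * base.beta`` at the highest; alpha unchanged.
    This emulates denser vegetation providing prey refugia.
    """
    if not 0.0 <= scenario_strength <= 1.0:
        raise CommunityValidationError("scenario_strength must be in [0, 1]")
    lo, hi = richness_range
    frac = 0.0 if hi == lo else (sown_richness - lo) / (hi - lo)
    frac = min(1.0, max(0.0, frac))
    beta = base.beta * (1.0 - scenario_strength * frac)
    return ScalarConfig(base.alpha, max(beta, math.ulp(0.0)))
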