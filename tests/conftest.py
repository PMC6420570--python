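import itertools

import numpy as np
import pytest

from motifweb.motifs import MOTIF_CODES, classify_triad
from motifweb.synthetic import GeneratorConfig, generate_design, generate_pool


@pytest.fixture(scope="session")
def small_cfg():
    """A scaled-down experiment: 24 plants, 80 consumers, 16 plots, 2 periods."""
    return GeneratorConfig(
        global_seed=7,
        n_plants=24,
        plant_group_counts=(8, 4, 8, 4),
        n_plant_families=8,
        n_consumers=80,
        richness_levels=(1, 2, 4, 8),
        plots_per_level_per_block=(1, 1, 1, 1),
        n_periods=2,
    )


@pytest.fixture(scope="session")
def small_pool(small_cfg):
    return generate_pool(small_cfg)


@pytest.fixture(scope="session")
def small_design(small_cfg, small_pool):
    return generate_design(small_cfg, small_pool)


@pytest.fixture(scope="session")
def small_community(small_pool, small_design):
    return small_pool.nodes, small_pool.links, small_design


def random_digraph(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    adj = (rng.random((n, n)) < p).astype(np.uint8)
    np.fill_diagonal(adj, 0)
    return adj


def brute_force_census(adj: np.ndarray) -> tuple[dict[str, int], int]:
    """Classify every C(n,3) triple one by one via classify_triad."""
    n = adj.shape[0]
    counts = dict.fromkeys(MOTIF_CODES, 0)
    disconnected = 0
    for trio in itertools.combinations(range(n), 3):
        edges = [
            (u, v) for u, v in itertools.permutations(trio, 2) if adj[u, v]
        ]
        cls = classify_triad(edges, nodes=trio)
        if cls == "disconnected":
            disconnected += 1
        else:
            counts[cls] += 1
    return counts, disconnected
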