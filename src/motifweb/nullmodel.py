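"""Degree-preserving randomisation of binary webs (Curveball algorithm).

A web is viewed as an incidence matrix with one row per consumer listing its
resources.  A trade picks two consumers and exchanges a random subset of the
resources exclusive to each, which leaves every row and column sum — hence
every node's in- and out-degree, the link total, and connectance — exactly
unchanged.  Because basal nodes have zero consumer-side degree, they can
never acquire resources, so "plants do not eat consumers" is preserved for
free.  Each null-ensemble member restarts from the original web with an
independent trade sequence (no chain autocorrelation between members).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .motifs import census_adjacency
from .webs import BinaryWeb

#: default number of trades per rewired sample, times the number of consumer rows
DEFAULT_TRADES_FACTOR = 5

#: lower bound on trades per sample: the factor-times-rows heuristic
#: under-mixes very small incidence matrices (chi-square diagnostics on
#: exhaustively enumerable margin classes), so tiny webs get extra trades
MIN_TRADES = 50


def curveball_trade(rows: list[set[int]], rng: np.random.Generator) -> list[set[int]]:
    """One Curveball trade on a list of per-consumer resource sets.

    Reference implementation on Python sets (the production path uses the
    compiled kernel); returns the same list, modified in place.  With fewer
    than two rows this is a no-op.
    """
    if len(rows) < 2:
        return rows
    a, b = rng.choice(len(rows), size=2, replace=False)
    a_only = list(rows[a] - rows[b])
    b_only = list(rows[b] - rows[a])
    if not a_only or not b_only:
        return rows
    pool = a_only + b_only
    perm = rng.permutation(len(pool))
    new_a = {pool[k] for k in perm[: len(a_only)]}
    new_b = {pool[k] for k in perm[len(a_only):]}
    rows[a] = (rows[a] - set(a_only)) | new_a
    rows[b] = (rows[b] - set(b_only)) | new_b
    return rows


def rewire(
    bweb: BinaryWeb,
    n_trades: int | None = None,
    rng_seed: int = 0,
    trades_factor: int = DEFAULT_TRADES_FACTOR,
) -> BinaryWeb:
    """Return a randomised copy of ``bweb`` after ``n_trades`` Curveball trades.

    Defaults to ``trades_factor`` times the number of consumer rows, with a
    floor of ``MIN_TRADES`` so that very small webs still mix.
    The node set and every node's in/out degree are identical to the input.
    """
    M = np.ascontiguousarray(bweb.adj.T).copy()  # rows = consumers
    rows = np.nonzero(M.sum(axis=1) > 0)[0].astype(np.int64)
    if n_trades is None:
        n_trades = max(trades_factor * rows.size, MIN_TRADES)
    if n_trades > 0 and rows.size >= 2:
        _kernels.curveball(M, rows, int(n_trades), int(rng_seed) % (2**32 - 1))
    return BinaryWeb(
        plot_id=bweb.plot_id,
        time_period=bweb.time_period,
        iteration=bweb.iteration,
        node_ids=list(bweb.node_ids),
        is_basal=bweb.is_basal.copy(),
        guilds=list(bweb.guilds),
        adj=np.ascontiguousarray(M.T),
    )


@dataclass(frozen=True)
class NullEnsembleStats:
    """Per-motif mean and SD of counts over R rewired webs."""

    mean: np.ndarray  # (13,)
    sd: np.ndarray  # (13,)
    R: int

    def __post_init__(self) -> None:
        if self.R < 2:
            raise ValueError("null ensemble needs R >= 2")


def null_ensemble(
    bweb: BinaryWeb,
    R: int = 250,
    n_trades: int | None = None,
    rng_seed: int = 0,
    trades_factor: int = DEFAULT_TRADES_FACTOR,
) -> NullEnsembleStats:
    """Census statistics over R independent rewirings of one web.

    Every member starts from ``bweb`` with its own trade sequence seeded from
    ``rng_seed``; the per-class mean and (population) standard deviation of
    the 13 motif counts are returned.
    """
    counts = np.empty((R, 13), dtype=np.float64)
    ss = np.random.SeedSequence(int(rng_seed) % (2**31 - 1))
    member_seeds = ss.generate_state(R, np.uint32) % (2**31 - 1)
    for r in range(R):
        rw = rewire(
            bweb, n_trades=n_trades, rng_seed=int(member_seeds[r]),
            trades_factor=trades_factor,
        )
        counts[r] = census_adjacency(rw.adj)
    return NullEnsembleStats(mean=counts.mean(axis=0), sd=counts.std(axis=0), R=R)
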