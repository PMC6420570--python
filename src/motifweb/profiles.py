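"""Motif representation profiles: z-scores against null webs, normalised.

For a sampled web with motif counts X and a null ensemble with per-class
mean Xbar and SD sigma, the representation of motif i is the z-score

    z_i = (X_i - Xbar_i) / sigma_i

and, because larger networks show more extreme raw z-scores, the profile is
normalised to unit Euclidean length:

    n_i = z_i / sqrt(sum_j z_j^2)

so profiles of webs of different sizes are comparable.  Positive n_i means
motif i is over-represented relative to the degree-preserving null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .motifs import census_adjacency
from .nullmodel import DEFAULT_TRADES_FACTOR, NullEnsembleStats, null_ensemble
from .webs import BinaryWeb, ProbabilisticWeb, consumer_subweb, iteration_seed, sample_binary_web


def z_score(observed: np.ndarray, null_stats: NullEnsembleStats) -> tuple[np.ndarray, int]:
    """Per-class z-scores with a finite convention for degenerate classes.

    Where sigma_i = 0 and X_i = Xbar_i the class is exactly at its null
    expectation and z_i = 0.  Where sigma_i = 0 but X_i != Xbar_i (rigid
    tiny webs), the difference is scaled by the smallest nonzero sigma of the
    ensemble (or 1 if all classes are rigid) to keep the direction without an
    infinity; the number of such classes is returned as a flag count.
    """
    observed = np.asarray(observed, dtype=np.float64)
    if observed.shape != null_stats.mean.shape:
        raise ValueError("shape mismatch between observed counts and null stats")
    diff = observed - null_stats.mean
    sd = null_stats.sd
    z = np.zeros_like(diff)
    ok = sd > 0
    z[ok] = diff[ok] / sd[ok]
    degenerate = (~ok) & (diff != 0)
    n_flagged = int(degenerate.sum())
    if n_flagged:
        fallback = sd[ok].min() if ok.any() else 1.0
        z[degenerate] = diff[degenerate] / fallback
    return z, n_flagged


def normalize_profile(z: np.ndarray) -> np.ndarray:
    """Scale a z-score vector to unit Euclidean norm (zero maps to zero)."""
    z = np.asarray(z, dtype=np.float64)
    if not np.all(np.isfinite(z)):
        raise ValueError("z-scores must be finite")
    norm = np.sqrt(np.sum(z**2))
    if norm == 0:
        return np.zeros_like(z)
    return z / norm


@dataclass(frozen=True)
class MotifProfile:
    """Iteration-mean motif representation of one plot-period web."""

    z: np.ndarray  # (13,) mean z-scores
    n: np.ndarray  # (13,) mean normalised scores
    n_se: np.ndarray  # (13,) Monte-Carlo SE of the normalised-score mean
    counts: np.ndarray  # (13,) mean motif counts
    scope: str
    plot_id: str = ""
    time_period: int = 0
    iterations: int = 1
    n_flagged: int = 0  # degenerate sigma=0 classes encountered (summed)


@dataclass
class _Accum:
    z: list = field(default_factory=list)
    n: list = field(default_factory=list)
    counts: list = field(default_factory=list)
    flagged: int = 0

    def add(self, counts: np.ndarray, stats: NullEnsembleStats) -> None:
        z, fl = z_score(counts, stats)
        self.z.append(z)
        self.n.append(normalize_profile(z))
        self.counts.append(counts)
        self.flagged += fl

    def finish(self, scope: str, pweb: ProbabilisticWeb, iterations: int) -> MotifProfile:
        z = np.array(self.z)
        n = np.array(self.n)
        return MotifProfile(
            z=z.mean(axis=0),
            n=n.mean(axis=0),
            n_se=n.std(axis=0, ddof=1) / np.sqrt(len(self.n)) if len(self.n) > 1
            else np.zeros(13),
            counts=np.array(self.counts).mean(axis=0),
            scope=scope,
            plot_id=pweb.plot_id,
            time_period=pweb.time_period,
            iterations=iterations,
            n_flagged=self.flagged,
        )


def web_profile(
    bweb: BinaryWeb, R: int = 250, n_trades: int | None = None, rng_seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """(counts, z, n, flags) of a single binary web against its own ensemble."""
    counts = census_adjacency(bweb.adj).astype(np.float64)
    stats = null_ensemble(bweb, R=R, n_trades=n_trades, rng_seed=rng_seed)
    z, fl = z_score(counts, stats)
    return counts, z, normalize_profile(z), fl


def profile_pipeline(
    pweb: ProbabilisticWeb,
    iterations: int = 50,
    R: int = 250,
    n_trades: int | None = None,
    global_seed: int = 0,
    trades_factor: int = DEFAULT_TRADES_FACTOR,
) -> tuple[MotifProfile, MotifProfile]:
    """Iteration-mean profiles of one plot-period, full web and consumer sub-web.

    Per iteration: sample the probability matrix, census the full web and its
    consumer sub-web, build an independent null ensemble for each scope, form
    z-scores, normalise *per iteration*, then average the normalised vectors
    over iterations.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if R < 2:
        raise ValueError("R must be >= 2")
    acc_full, acc_free = _Accum(), _Accum()
    for it in range(iterations):
        seed = iteration_seed(global_seed, pweb.plot_id, pweb.time_period, it)
        bweb = sample_binary_web(pweb, seed, iteration=it)
        sub = consumer_subweb(bweb)
        for acc, web, tag in ((acc_full, bweb, 1), (acc_free, sub, 2)):
            counts = census_adjacency(web.adj).astype(np.float64)
            stats = null_ensemble(
                web, R=R, n_trades=n_trades, trades_factor=trades_factor,
                rng_seed=iteration_seed(global_seed + tag, pweb.plot_id, pweb.time_period, it),
            )
            acc.add(counts, stats)
    return (
        acc_full.finish("full", pweb, iterations),
        acc_free.finish("consumer_subweb", pweb, iterations),
    )
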