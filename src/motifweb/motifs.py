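"""Classification and census of the 13 connected directed triads.

Excluding cannibalism, three nodes can form 64 labelled digraphs which fall
into 16 isomorphism classes; 13 of them are weakly connected.  Classes whose
dyads are all single feeding links carry an ``s`` code and those with at
least one double (bidirectional) link a ``d`` code:

=====  ======  ==========================================================
code   triad   ecology
=====  ======  ==========================================================
s1     021C    tri-trophic chain (plant -> herbivore -> predator)
s2     030T    omnivory: the top consumer feeds on both other nodes
s3     030C    directed three-cycle (feed-forward loop)
s4     021U    apparent competition: two resources share one consumer
s5     021D    exploitative competition: one resource, two consumers
d1-d8  111D, 111U, 120D, 120U, 120C, 201, 210, 300 (mutual-dyad classes)
=====  ======  ==========================================================

The census counts *induced* subgraphs: every unordered triple contributes to
exactly one class (or to "disconnected"), so an omnivory triple is not also
counted as the chain and competition motifs embedded in it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .webs import BinaryWeb, ProbabilisticWeb, consumer_subweb, iteration_seed, sample_binary_web

#: the 16 directed-triad types in conventional census order
TRIAD16 = (
    "003", "012", "102", "021D", "021U", "021C", "111D", "111U",
    "030T", "030C", "201", "120D", "120U", "120C", "210", "300",
)

#: motif codes in reporting order; s = single links only, d = >=1 double link
MOTIF_CODES = ("s1", "s2", "s3", "s4", "s5", "d1", "d2", "d3", "d4", "d5", "d6", "d7", "d8")

#: motif code -> conventional triad-type name
MOTIF_TO_TRIAD = {
    "s1": "021C", "s2": "030T", "s3": "030C", "s4": "021U", "s5": "021D",
    "d1": "111D", "d2": "111U", "d3": "120D", "d4": "120U", "d5": "120C",
    "d6": "201", "d7": "210", "d8": "300",
}

TRIAD_TO_MOTIF = {v: k for k, v in MOTIF_TO_TRIAD.items()}

#: aggregate reported as "other": the loop plus all double-link classes
OTHER_CODES = ("s3",) + tuple(c for c in MOTIF_CODES if c.startswith("d"))
COMMON_CODES = ("s1", "s2", "s4", "s5")

_PAIRS = ((0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1))


def _edges_of(code: int) -> tuple[tuple[int, int], ...]:
    return tuple(_PAIRS[b] for b in range(6) if code >> b & 1)


def _recode(code: int, perm: tuple[int, int, int]) -> int:
    es = {(perm[u], perm[v]) for (u, v) in _edges_of(code)}
    out = 0
    for i, p in enumerate(_PAIRS):
        if p in es:
            out |= 1 << i
    return out


def _canonical(code: int) -> int:
    return min(_recode(code, p) for p in itertools.permutations((0, 1, 2)))


def _is_connected(code: int) -> bool:
    und = [set() for _ in range(3)]
    for u, v in _edges_of(code):
        und[u].add(v)
        und[v].add(u)
    seen = {0}
    stack = [0]
    while stack:
        for w in und[stack.pop()]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == 3

# canonical 6-bit code of a representative labelled digraph per triad type
_TYPE_REPRESENTATIVE = {
    "003": (), "012": ((0, 1),), "102": ((0, 1), (1, 0)),
    "021D": ((0, 1), (0, 2)), "021U": ((1, 0), (2, 0)), "021C": ((0, 1), (1, 2)),
    "111D": ((0, 1), (1, 0), (2, 0)), "111U": ((0, 1), (1, 0), (0, 2)),
    "030T": ((0, 1), (0, 2), (1, 2)), "030C": ((0, 1), (1, 2), (2, 0)),
    "201": ((0, 1), (1, 0), (0, 2), (2, 0)),
    "120D": ((1, 0), (0, 2), (2, 0), (1, 2)), "120U": ((0, 1), (1, 0), (0, 2), (1, 2)),
    "120C": ((0, 1), (1, 0), (2, 0), (1, 2)),
    "210": ((0, 1), (1, 0), (0, 2), (2, 0), (1, 2)),
    "300": tuple((u, v) for u in range(3) for v in range(3) if u != v),
}


def _build_tables() -> tuple[np.ndarray, dict[int, str]]:
    """Enumerate all 64 labelled triads and map them to the 16 types."""
    canon_to_type: dict[int, str] = {}
    for name, edges in _TYPE_REPRESENTATIVE.items():
        code = 0
        for i, p in enumerate(_PAIRS):
            if p in edges:
                code |= 1 << i
        canon_to_type[_canonical(code)] = name
    assert len(canon_to_type) == 16
    table = np.empty(64, dtype=np.int64)
    for code in range(64):
        table[code] = TRIAD16.index(canon_to_type[_canonical(code)])
    return table, canon_to_type

#: labelled 6-bit code -> index into TRIAD16
CODE16_TABLE, _CANON_TO_TYPE = _build_tables()

#: indices of the 13 connected classes (MOTIF_CODES order) within TRIAD16
_MOTIF16_INDEX = np.array([TRIAD16.index(MOTIF_TO_TRIAD[c]) for c in MOTIF_CODES])


@dataclass(frozen=True)
class MotifCounts:
    """Counts (or iteration means) of the 13 connected triad classes."""

    counts: np.ndarray  # (13,) in MOTIF_CODES order
    scope: str  # 'full' or 'consumer_subweb'
    plot_id: str = ""
    time_period: int = 0

    def as_dict(self) -> dict[str, float]:
        return dict(zip(MOTIF_CODES, self.counts.tolist()))

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def classify_triad(edges, nodes=None) -> str:
    """Isomorphism class of a labelled 3-node digraph.

    Parameters
    ----------
    edges : iterable of (u, v) pairs
        Directed edges among exactly three labelled nodes.
    nodes : iterable, optional
        The three node labels; inferred from ``edges`` if omitted (requires
        all three nodes to appear in some edge).

    Returns
    -------
    str
        A motif code from :data:`MOTIF_CODES`, or ``"disconnected"``.
    """
    edges = list(edges)
    labels = set(nodes) if nodes is not None else {x for e in edges for x in e}
    if len(labels) != 3:
        raise ValueError(f"expected exactly 3 nodes, got {sorted(map(str, labels))}")
    order = {lab: k for k, lab in enumerate(sorted(labels, key=str))}
    code = 0
    for u, v in edges:
        if u == v:
            raise ValueError(f"self-loop on {u!r} not allowed")
        if u not in order or v not in order:
            raise ValueError(f"edge ({u!r}, {v!r}) uses an unknown node")
        code |= 1 << _PAIRS.index((order[u], order[v]))
    triad = TRIAD16[CODE16_TABLE[code]]
    return TRIAD_TO_MOTIF.get(triad, "disconnected")


def census_adjacency(adj: np.ndarray) -> np.ndarray:
    """13-vector of induced connected-triad counts for an adjacency matrix."""
    adj = np.ascontiguousarray(adj, dtype=np.uint8)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if np.any(np.diagonal(adj)):
        raise ValueError("self-loops are not allowed")
    c16 = _kernels.census16(adj, CODE16_TABLE)
    return c16[_MOTIF16_INDEX].copy()


def census(bweb: BinaryWeb) -> MotifCounts:
    """Induced triad census of one binary web (13 connected classes)."""
    return MotifCounts(
        counts=census_adjacency(bweb.adj),
        scope="full",
        plot_id=bweb.plot_id,
        time_period=bweb.time_period,
    )


def census_profile(
    pweb: ProbabilisticWeb,
    iterations: int = 50,
    global_seed: int = 0,
) -> tuple[MotifCounts, MotifCounts, np.ndarray]:
    """Mean motif counts over sampled webs, full and free-floating.

    Samples the probability matrix ``iterations`` times; for each draw the
    full web and its consumer sub-web are censused (the same draw is reused
    for both scopes).  Returns ``(full_mean, freefloating_mean, grounded)``
    where ``grounded[i] = (full_i - free_i) / full_i`` for classes with
    ``full_i > 0`` and NaN elsewhere.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    full = np.zeros(13, dtype=np.float64)
    free = np.zeros(13, dtype=np.float64)
    for it in range(iterations):
        seed = iteration_seed(global_seed, pweb.plot_id, pweb.time_period, it)
        bweb = sample_binary_web(pweb, seed, iteration=it)
        full += census_adjacency(bweb.adj)
        free += census_adjacency(consumer_subweb(bweb).adj)
    full /= iterations
    free /= iterations
    with np.errstate(invalid="ignore", divide="ignore"):
        grounded = np.where(full > 0, (full - free) / full, np.nan)
    mk = lambda c, scope: MotifCounts(c, scope, pweb.plot_id, pweb.time_period)
    return mk(full, "full"), mk(free, "consumer_subweb"), grounded
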