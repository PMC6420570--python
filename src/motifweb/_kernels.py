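"""Numba kernels for the directed triad census and Curveball trading.

The census follows the linked-dyad enumeration strategy (classify only the
triads that contain at least one feeding link; recover the fully
disconnected count by subtraction), which makes the cost proportional to the
number of connected triples rather than C(n, 3).  The Curveball kernel trades
exclusive resources between two consumer rows of the incidence view of a web,
which preserves every row and column sum exactly.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def census16(adj, code16):
    """Counts of the 16 directed triad isomorphism types.

    Parameters
    ----------
    adj : (n, n) uint8 array
        adj[i, j] = 1 iff there is a directed edge i -> j.  Zero diagonal.
    code16 : (64,) int64 array
        Lookup from the 6-bit labelled-triad code to the triad type index.

    Returns
    -------
    (16,) int64 array of triad counts, summing to C(n, 3).
    """
    n = adj.shape[0]
    counts = np.zeros(16, np.int64)
    if n < 3:
        return counts

    # undirected neighbour lists
    deg = np.zeros(n, np.int64)
    for i in range(n):
        for j in range(n):
            if i != j and (adj[i, j] or adj[j, i]):
                deg[i] += 1
    maxd = 0
    for i in range(n):
        if deg[i] > maxd:
            maxd = deg[i]
    nbr = np.empty((n, maxd if maxd > 0 else 1), np.int64)
    fill = np.zeros(n, np.int64)
    for i in range(n):
        for j in range(n):
            if i != j and (adj[i, j] or adj[j, i]):
                nbr[i, fill[i]] = j
                fill[i] += 1

    mark = np.full(n, -1, np.int64)
    buf = np.empty(n, np.int64)
    for u in range(n):
        for iu in range(deg[u]):
            v = nbr[u, iu]
            if v <= u:
                continue
            stamp = u * n + v
            m = 0
            for k in range(deg[u]):
                w = nbr[u, k]
                if w != v and mark[w] != stamp:
                    mark[w] = stamp
                    buf[m] = w
                    m += 1
            for k in range(deg[v]):
                w = nbr[v, k]
                if w != u and mark[w] != stamp:
                    mark[w] = stamp
                    buf[m] = w
                    m += 1
            # triads where the third node touches neither u nor v
            if adj[u, v] and adj[v, u]:
                counts[2] += n - m - 2  # 102: mutual dyad + isolate
            else:
                counts[1] += n - m - 2  # 012: single arc + isolate
            # triads with >= 2 linked dyads: count each exactly once
            for k in range(m):
                w = buf[k]
                if v < w or (u < w and w < v and adj[u, w] == 0 and adj[w, u] == 0):
                    code = (
                        adj[u, v]
                        + 2 * adj[v, u]
                        + 4 * adj[u, w]
                        + 8 * adj[w, u]
                        + 16 * adj[v, w]
                        + 32 * adj[w, v]
                    )
                    counts[code16[code]] += 1

    total = n * (n - 1) * (n - 2) // 6
    s = np.int64(0)
    for t in range(1, 16):
        s += counts[t]
    counts[0] = total - s
    return counts


@njit(cache=True)
def curveball(M, rows, n_trades, seed):
    """Apply ``n_trades`` Curveball trades to incidence matrix ``M`` in place.

    M[c, r] = 1 iff consumer ``c`` feeds on resource ``r`` (node indices are
    shared between the two axes, so M is the transpose of the directed
    adjacency matrix).  ``rows`` holds the indices of tradeable (consumer)
    rows.  Columns equal to either traded row index are held fixed so the
    diagonal stays zero (no cannibalistic links are ever created).  Row and
    column sums are invariant.
    """
    nr = rows.size
    if nr < 2:
        return
    nc = M.shape[1]
    np.random.seed(seed)
    bufa = np.empty(nc, np.int64)
    bufb = np.empty(nc, np.int64)
    pool = np.empty(nc, np.int64)
    for _ in range(n_trades):
        a = rows[np.random.randint(0, nr)]
        b = rows[np.random.randint(0, nr)]
        if a == b:
            continue
        na = 0
        nb = 0
        for c in range(nc):
            if c == a or c == b:
                continue
            if M[a, c] == 1:
                if M[b, c] == 0:
                    bufa[na] = c
                    na += 1
            elif M[b, c] == 1:
                bufb[nb] = c
                nb += 1
        if na == 0 or nb == 0:
            continue
        tot = na + nb
        for i in range(na):
            pool[i] = bufa[i]
        for i in range(nb):
            pool[na + i] = bufb[i]
        for i in range(tot - 1, 0, -1):  # Fisher-Yates
            j = np.random.randint(0, i + 1)
            tmp = pool[i]
            pool[i] = pool[j]
            pool[j] = tmp
        for i in range(tot):
            c = pool[i]
            if i < na:
                M[a, c] = 1
                M[b, c] = 0
            else:
                M[a, c] = 0
                M[b, c] = 1
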