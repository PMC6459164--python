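"""Numba kernels for the MINE maximal information coefficient.

The estimator follows the canonical MINE scheme: one axis is equipartitioned
into ``b`` rows (ties kept together), the other axis is partitioned into at
most ``a`` columns by a dynamic program whose cut points are restricted to
clump boundaries (maximal runs of consecutive points sharing a row), capped
at ``clump_factor * a`` superclumps. Because the row partition is fixed,
maximizing mutual information is equivalent to minimizing the conditional
entropy H(rows | columns), which is additive over columns — the quantity the
DP minimizes.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def equipartition(vals_sorted, b):
    """Assign sorted values to at most ``b`` rows of near-equal size.

    Tied values always land in the same row. Returns (row index per sorted
    position, number of rows actually used).
    """
    n = vals_sorted.shape[0]
    rows = np.empty(n, np.int64)
    i = 0
    row = 0
    in_row = 0
    desired = n / b
    while i < n:
        j = i + 1
        while j < n and vals_sorted[j] == vals_sorted[i]:
            j += 1
        s = j - i
        if (
            in_row > 0
            and row < b - 1
            and abs(in_row + s - desired) >= abs(in_row - desired)
        ):
            row += 1
            in_row = 0
            desired = (n - i) / (b - row)
        for t in range(i, j):
            rows[t] = row
        in_row += s
        i = j
    return rows, row + 1


@njit(cache=True)
def optimize_axis(rows, block_ends, n_rows, amax, cap):
    """Maximize I(columns; rows) over column partitions with <= a columns.

    ``rows``: row index per point in column-axis sort order.
    ``block_ends``: cumulative point counts at positions where the
    column-axis value changes (cuts inside a tie block are not allowed).
    Returns ``out`` with ``out[a]`` = max mutual information (bits) over
    grids with at most ``a`` columns, for a = 2..amax.
    """
    n = rows.shape[0]
    m = block_ends.shape[0]
    bc = np.zeros((m, n_rows), np.int64)
    start = 0
    for i in range(m):
        for p in range(start, block_ends[i]):
            bc[i, rows[p]] += 1
        start = block_ends[i]

    # clumps: merge consecutive blocks that are pure in the same row
    ccounts = np.zeros((m, n_rows), np.int64)
    crow = np.full(m, -2, np.int64)
    ck = 0
    for i in range(m):
        r_pure = -1
        nz = 0
        for r in range(n_rows):
            if bc[i, r] > 0:
                nz += 1
                r_pure = r
        pure = nz == 1
        if ck > 0 and pure and crow[ck - 1] == r_pure:
            for r in range(n_rows):
                ccounts[ck - 1, r] += bc[i, r]
        else:
            for r in range(n_rows):
                ccounts[ck, r] = bc[i, r]
            crow[ck] = r_pure if pure else -2
            ck += 1

    if ck > cap:
        # superclumps: equipartition clumps by point count
        sc = np.zeros((cap, n_rows), np.int64)
        j = 0
        in_cur = 0
        placed = 0
        desired = n / cap
        for i in range(ck):
            s = 0
            for r in range(n_rows):
                s += ccounts[i, r]
            if (
                in_cur > 0
                and j < cap - 1
                and abs(in_cur + s - desired) >= abs(in_cur - desired)
            ):
                j += 1
                in_cur = 0
                desired = (n - placed) / (cap - j)
            for r in range(n_rows):
                sc[j, r] += ccounts[i, r]
            in_cur += s
            placed += s
        k = j + 1
        cc = sc
    else:
        k = ck
        cc = ccounts

    cum = np.zeros((k + 1, n_rows), np.int64)
    for i in range(k):
        for r in range(n_rows):
            cum[i + 1, r] = cum[i, r] + cc[i, r]

    hq = 0.0
    for r in range(n_rows):
        c = cum[k, r]
        if c > 0:
            hq -= (c / n) * np.log2(c / n)

    # cost[s, t]: contribution of a column spanning clumps (s, t] to H(Q|P)
    cost = np.zeros((k + 1, k + 1), np.float64)
    for s in range(k + 1):
        for t in range(s + 1, k + 1):
            nseg = 0
            for r in range(n_rows):
                nseg += cum[t, r] - cum[s, r]
            acc = 0.0
            for r in range(n_rows):
                c = cum[t, r] - cum[s, r]
                if 0 < c < nseg:
                    acc += (c / n) * np.log2(nseg / c)
            cost[s, t] = acc

    out = np.zeros(amax + 1, np.float64)
    f_prev = np.empty(k + 1, np.float64)
    f_cur = np.empty(k + 1, np.float64)
    for t in range(1, k + 1):
        f_prev[t] = cost[0, t]
    best_hqp = f_prev[k]
    for l in range(2, amax + 1):
        if l <= k:
            for t in range(l, k + 1):
                best = np.inf
                for s in range(l - 1, t):
                    v = f_prev[s] + cost[s, t]
                    if v < best:
                        best = v
                f_cur[t] = best
            if f_cur[k] < best_hqp:
                best_hqp = f_cur[k]
            tmp = f_prev
            f_prev = f_cur
            f_cur = tmp
        out[l] = hq - best_hqp
    return out
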