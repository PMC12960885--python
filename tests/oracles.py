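"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own algorithms: reachability is a
plain breadth-first search, distances are all-pairs scans, class lookups are
linear interval scans, component counting is union-find, and the t statistic
is the textbook pooled-variance formula.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def bfs_coastal_land(elevation, sea, barriers=None, lakes=None, threshold=2.0):
    """Breadth-first reachability from sea cells over low-elevation land (4-conn)."""
    n_rows, n_cols = elevation.shape
    barriers = np.zeros_like(sea) if barriers is None else barriers
    lakes = np.zeros_like(sea) if lakes is None else lakes
    candidate = (elevation <= threshold) & ~sea & ~barriers & ~lakes
    traversable = candidate | sea
    visited = np.zeros_like(sea)
    queue = deque(zip(*np.nonzero(sea)))
    visited[sea] = True
    while queue:
        r, c = queue.popleft()
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= rr < n_rows and 0 <= cc < n_cols and traversable[rr, cc] \
                    and not visited[rr, cc]:
                visited[rr, cc] = True
                queue.append((rr, cc))
    return visited & candidate


def brute_min_cell_distance(rows_a, cols_a, rows_b, cols_b, cell_size):
    """All-pairs minimum centre-to-centre distance between two cell sets (m)."""
    if len(rows_b) == 0:
        return math.inf
    dr = np.asarray(rows_a)[:, None] - np.asarray(rows_b)[None, :]
    dc = np.asarray(cols_a)[:, None] - np.asarray(cols_b)[None, :]
    return float(np.sqrt(dr * dr + dc * dc).min() * cell_size)


def scan_distance_class(d, breaks=(100.0, 400.0, 1000.0, 5000.0), values=(4, 3, 2, 1)):
    """Linear interval scan for the distance-class lookup."""
    for brk, val in zip(breaks, values):
        if d <= brk:
            return val
    return 0


def scan_proportion_class(p, breaks=(20.0, 40.0, 60.0, 80.0), values=(1, 2, 3, 4)):
    """Linear interval scan for the proportion-class lookup."""
    result = 0
    for brk, val in zip(breaks, values):
        if p >= brk:
            result = val
    return result


def union_find_components(mask):
    """Number of 4-connected components of a boolean mask, by union-find."""
    n_rows, n_cols = mask.shape
    parent = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for r, c in zip(*np.nonzero(mask)):
        parent[(r, c)] = (r, c)
    for r, c in zip(*np.nonzero(mask)):
        for rr, cc in ((r + 1, c), (r, c + 1)):
            if 0 <= rr < n_rows and 0 <= cc < n_cols and mask[rr, cc]:
                union((r, c), (rr, cc))
    return len({find(x) for x in parent})


def pooled_t(a, b):
    """Textbook two-sample pooled-variance Student t and two-sided p."""
    from scipy.stats import t as t_dist

    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * t_dist.sf(abs(t), df)
    return df, t, p


def confusion_balanced_accuracy(predicted, actual):
    """Balanced accuracy from an explicit confusion matrix (vacuous rate = 1)."""
    predicted = np.asarray(predicted, dtype=bool)
    actual = np.asarray(actual, dtype=bool)
    rates = []
    for cls in (True, False):
        sel = actual == cls
        rates.append(float(np.mean(predicted[sel] == cls)) if sel.any() else 1.0)
    return float(np.mean(rates))
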