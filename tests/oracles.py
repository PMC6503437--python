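"""Independent brute-force oracles used by the test suite.

Each function recomputes a quantity from first principles (enumeration,
textbook formula, Floyd-Warshall) without touching the package's
implementation paths.
"""

import itertools
import math

import numpy as np


def union_by_pairwise_merge(pathways):
    """Edge/node union via explicit pairwise merging of normalized edge sets."""
    merged: set = set()
    for pathway in pathways:
        edges = {frozenset(e) for e in pathway if e[0] != e[1]}
        merged = merged | edges
    nodes = set(itertools.chain.from_iterable(merged))
    return nodes, merged


def floyd_warshall(nodes, edges):
    """All-pairs shortest hop counts by the classic triple loop."""
    n = len(nodes)
    idx = {g: k for k, g in enumerate(nodes)}
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for a, b in edges:
        d[idx[a], idx[b]] = 1.0
        d[idx[b], idx[a]] = 1.0
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    return d


def midrank(x):
    """Average ranks with midrank ties, computed by sorting and grouping."""
    x = np.asarray(x, float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_via_midrank_pearson(x, y):
    """Spearman rho as the Pearson correlation of midranks."""
    rx, ry = midrank(x) - np.mean(midrank(x)), midrank(y) - np.mean(midrank(y))
    denom = math.sqrt((rx**2).sum() * (ry**2).sum())
    return float((rx * ry).sum() / denom)


def welch_t_formula(a, b):
    """Welch two-sample t and its two-sided p from the textbook formulas."""
    from scipy import stats

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, p


def kendall_tau_b_enumeration(x, y):
    """tau-b by O(n^2) pair enumeration with explicit tie bookkeeping.

    Returns NaN when all pairs are tied in x or in y.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    conc = disc = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0:
                ties_x += 1
            if dy == 0:
                ties_y += 1
            if dx == 0 or dy == 0:
                continue
            if dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) // 2
    if ties_x == n0 or ties_y == n0:
        return float("nan")
    return (conc - disc) / math.sqrt((n0 - ties_x) * (n0 - ties_y))


def chi2_4df_survival(x):
    """Closed-form upper tail of a chi-square with 4 degrees of freedom."""
    return math.exp(-x / 2.0) * (1.0 + x / 2.0)
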