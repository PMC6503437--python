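"""Decay-of-differential-expression test: does differential expression around
a gene fall off with geodesic distance from it (self-contained null)?

The observed statistic at radius r is the Kendall tau-b rank correlation

    D_i(r) = tau_b({g_j : 0 < d_ij <= r}, {d_ij : 0 < d_ij <= r})

over the assayed neighborhood; a decaying pattern gives negative values.
Significance comes from phenotype-label permutations: each permutation
recomputes the gene-level statistics g*_j for all genes (preserving the
inter-gene correlation structure) and the discordance D*_i(r).  The
empirical p-value is lower-tail with add-one smoothing,
p = (1 + #{D* <= D_obs}) / (B + 1).

Distances are small integers, so ties in the distance vector are the norm;
tau-b's tie correction is essential.  A single incremental pass per gene
scores every radius at once: genes are ordered by distance, and concordant-
minus-discordant pair counts are accumulated as each distance shell is
appended (pairs within a shell are distance-tied and contribute nothing to
the numerator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import stats

#: Minimum assayed-neighborhood size for which tau-b is attempted; smaller
#: neighborhoods cannot exhibit a detectable decay and get p = 1.
MIN_NEIGHBORHOOD = 3


def kendall_tau_b(x, y) -> float:
    """Kendall tau-b with tie correction, (C - D)/sqrt((n0-n1)(n0-n2)).

    Returns NaN when all pairs are tied in x or in y (the coefficient is
    undefined; callers treat this as "no signal").
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must be equal-length vectors of size >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    tau = stats.kendalltau(x, y, variant="b").statistic
    return float(tau)


def observed_discordance(g_values, distances) -> float:
    """tau_b between DE magnitudes and distances over one neighborhood.

    NaN when the neighborhood has fewer than ``MIN_NEIGHBORHOOD`` members or
    when either vector is all-tied.
    """
    g_values = np.asarray(g_values, float)
    distances = np.asarray(distances, float)
    if g_values.size < MIN_NEIGHBORHOOD:
        return float("nan")
    return kendall_tau_b(g_values, distances)


@njit(cache=True)
def _prefix_pair_counts(x, grp):  # pragma: no cover - exercised via wrapper
    """Cumulative concordant-minus-discordant and x-tie pair counts.

    ``x`` is (n_rows, n) with columns sorted by non-decreasing group label
    ``grp`` (the integer distances).  After processing column k, ``s[b, k]``
    holds C - D over all pairs among columns 0..k whose groups differ, and
    ``t[b, k]`` the number of x-tied pairs (any groups).
    """
    n_rows, n = x.shape
    s = np.zeros((n_rows, n))
    t = np.zeros((n_rows, n))
    for b in range(n_rows):
        acc_s = 0.0
        acc_t = 0.0
        for k in range(n):
            xk = x[b, k]
            gk = grp[k]
            for j in range(k):
                if grp[j] == gk:
                    if x[b, j] == xk:
                        acc_t += 1.0
                else:
                    if x[b, j] < xk:
                        acc_s += 1.0
                    elif x[b, j] > xk:
                        acc_s -= 1.0
                    else:
                        acc_t += 1.0
            s[b, k] = acc_s
            t[b, k] = acc_t
    return s, t


def prefix_tau_b(values: np.ndarray, distances: np.ndarray, radii: np.ndarray):
    """tau_b of every row of ``values`` against ``distances``, at every radius.

    ``values`` is (n_rows, n); ``distances`` the integer distance of each
    column.  For radius r only columns with distance <= r enter.  Returns an
    (n_rows, len(radii)) array; entries are NaN where tau-b is undefined
    (prefix < 2, all x tied, or all distances tied).
    """
    values = np.atleast_2d(np.asarray(values, float))
    d = np.asarray(distances)
    order = np.argsort(d, kind="stable")
    d_sorted = d[order].astype(np.int64)
    x = np.ascontiguousarray(values[:, order])
    s, t1 = _prefix_pair_counts(x, d_sorted)

    # distance-tie pair count per prefix: sum over shells of m*(m-1)/2
    n = d_sorted.size
    same = np.concatenate([[0], (np.diff(d_sorted) == 0).astype(np.int64)])
    run = np.zeros(n, dtype=np.int64)  # shell-internal index of each column
    for k in range(1, n):
        run[k] = run[k - 1] + 1 if same[k] else 0
    t2 = np.cumsum(run).astype(float)  # adding k-th shell member adds run[k] tied pairs

    bounds = np.searchsorted(d_sorted, np.asarray(radii), side="right")
    out = np.full((values.shape[0], len(radii)), np.nan)
    for col, nb in enumerate(bounds):
        if nb < 2:
            continue
        n0 = nb * (nb - 1) / 2.0
        n2 = t2[nb - 1]
        if n2 == n0:  # all distances tied
            continue
        n1 = t1[:, nb - 1]
        denom = (n0 - n1) * (n0 - n2)
        with np.errstate(invalid="ignore", divide="ignore"):
            tau = np.where(denom > 0, s[:, nb - 1] / np.sqrt(np.maximum(denom, 1e-300)), np.nan)
        out[:, col] = tau
    return out


@dataclass
class DecayResult:
    """Per-radius observed discordance and permutation p-values for one gene."""

    gene: str
    radii: np.ndarray
    d_obs: np.ndarray  # tau_b, NaN where undefined
    p: np.ndarray  # p^D_i(r) in (0, 1]
    n_neighbors: np.ndarray
    b: int  # number of permutations


def decay_pvalue_curve(
    g_obs: np.ndarray,
    g_null: np.ndarray,
    distances: np.ndarray,
    diameter: int,
    gene: str = "",
    min_neighborhood: int = MIN_NEIGHBORHOOD,
    strict_tail: bool = False,
) -> DecayResult:
    """Observed discordance and permutation p-values at radii 1..diameter.

    ``g_obs`` holds the observed |t| of the assayed on-network genes j != i,
    ``g_null`` the (B, n) permuted statistics (one shared set of label
    permutations), ``distances`` the matching d_ij.  Neighborhoods smaller
    than ``min_neighborhood``, or with the statistic undefined, get p = 1
    and D = NaN.  ``strict_tail`` switches the tail count from ``D* <= D``
    to the strict ``D* < D`` (no add-one change).
    """
    g_obs = np.asarray(g_obs, float)
    g_null = np.atleast_2d(np.asarray(g_null, float))
    d = np.asarray(distances)
    n_perm = g_null.shape[0]
    radii = np.arange(1, diameter + 1)

    stacked = np.vstack([g_obs[None, :], g_null])
    taus = prefix_tau_b(stacked, d, radii)
    d_curve = taus[0]
    null_curve = taus[1:]

    order = np.argsort(d, kind="stable")
    bounds = np.searchsorted(d[order], radii, side="right")

    p = np.ones(diameter, dtype=float)
    for k in range(diameter):
        if bounds[k] < min_neighborhood or not np.isfinite(d_curve[k]):
            d_curve[k] = np.nan
            continue
        null_k = null_curve[:, k]
        null_k = np.where(np.isfinite(null_k), null_k, 0.0)  # no-signal sentinel
        if strict_tail:
            count = np.count_nonzero(null_k < d_curve[k])
        else:
            count = np.count_nonzero(null_k <= d_curve[k])
        p[k] = (1.0 + count) / (n_perm + 1.0)

    return DecayResult(
        gene=gene,
        radii=radii,
        d_obs=d_curve,
        p=p,
        n_neighbors=bounds.astype(int),
        b=n_perm,
    )
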