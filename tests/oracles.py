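"""Independent brute-force oracles used only by the test suite.

Everything here is deliberately naive and shares no code with the package:
full-complex boundary-matrix reduction for Vietoris-Rips barcodes, GF(2)
rank computations for Betti numbers, scipy's MST for dimension-0 deaths,
and exhaustive k-center search.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform


def naive_vr_barcodes(points: np.ndarray, maxdim: int) -> dict[int, list[tuple[float, float]]]:
    """Barcodes by textbook column reduction over Z/2 on the full complex.

    Simplices up to dimension maxdim+1, filtration value = max pairwise
    distance, order (value, dim, lexicographic vertices).  Returns finite
    and infinite bars per dimension, zero-persistence pairs dropped.
    """
    n = len(points)
    dm = squareform(pdist(points)) if n > 1 else np.zeros((1, 1))

    simplices = []  # (value, dim, vertex tuple)
    for d in range(0, maxdim + 2):
        for verts in itertools.combinations(range(n), d + 1):
            if d == 0:
                val = 0.0
            else:
                val = max(dm[a, b] for a, b in itertools.combinations(verts, 2))
            simplices.append((val, d, verts))
    simplices.sort(key=lambda s: (s[0], s[1], s[2]))
    index_of = {s[2]: i for i, s in enumerate(simplices)}

    columns = []
    for val, d, verts in simplices:
        if d == 0:
            columns.append(set())
        else:
            columns.append({index_of[f] for f in itertools.combinations(verts, d)})

    low_to_col: dict[int, int] = {}
    pairs = []  # (birth index, death index)
    essential = set(range(len(simplices)))
    for j, col in enumerate(columns):
        while col:
            low = max(col)
            if low not in low_to_col:
                break
            col ^= columns[low_to_col[low]]
        if col:
            low = max(col)
            low_to_col[low] = j
            pairs.append((low, j))
            essential.discard(low)
            essential.discard(j)
        columns[j] = col

    bars: dict[int, list[tuple[float, float]]] = {d: [] for d in range(maxdim + 1)}
    for i, j in pairs:
        val_b, dim_b, _ = simplices[i]
        val_d, _, _ = simplices[j]
        if dim_b <= maxdim and val_d > val_b:
            bars[dim_b].append((val_b, val_d))
    for i in essential:
        val_b, dim_b, _ = simplices[i]
        if dim_b <= maxdim:
            bars[dim_b].append((val_b, np.inf))
    for d in bars:
        bars[d].sort()
    return bars


def betti_numbers(points: np.ndarray, t: float, maxdim: int) -> list[int]:
    """Betti numbers of the VR complex at scale t by GF(2) rank."""
    n = len(points)
    dm = squareform(pdist(points)) if n > 1 else np.zeros((1, 1))

    simp: dict[int, list[tuple]] = {}
    for d in range(0, maxdim + 2):
        simp[d] = [
            v
            for v in itertools.combinations(range(n), d + 1)
            if d == 0
            or max(dm[a, b] for a, b in itertools.combinations(v, 2)) <= t
        ]

    def boundary_rank(d: int) -> int:
        rows = {s: i for i, s in enumerate(simp[d - 1])}
        cols = simp[d]
        if not cols or not rows:
            return 0
        M = np.zeros((len(rows), len(cols)), dtype=np.uint8)
        for j, verts in enumerate(cols):
            for f in itertools.combinations(verts, d):
                M[rows[f], j] = 1
        return gf2_rank(M)

    betti = []
    for d in range(maxdim + 1):
        rank_d = boundary_rank(d) if d >= 1 else 0
        rank_d1 = boundary_rank(d + 1)
        betti.append(len(simp[d]) - rank_d - rank_d1)
    return betti


def gf2_rank(M: np.ndarray) -> int:
    M = M.copy() % 2
    rank = 0
    n_rows, n_cols = M.shape
    row = 0
    for col in range(n_cols):
        pivot = None
        for r in range(row, n_rows):
            if M[r, col]:
                pivot = r
                break
        if pivot is None:
            continue
        M[[row, pivot]] = M[[pivot, row]]
        for r in range(n_rows):
            if r != row and M[r, col]:
                M[r] ^= M[row]
        row += 1
        rank += 1
        if row == n_rows:
            break
    return rank


def mst_death_multiset(points: np.ndarray) -> np.ndarray:
    """Sorted positive MST edge weights via scipy's independent routine."""
    dm = squareform(pdist(points))
    mst = minimum_spanning_tree(dm).toarray()
    w = mst[mst > 0]
    return np.sort(w)


def kcenter_optimum(points: np.ndarray, k: int) -> float:
    """Exact k-center covering radius by brute force over all k-subsets."""
    dm = squareform(pdist(points)) if len(points) > 1 else np.zeros((1, 1))
    best = np.inf
    for subset in itertools.combinations(range(len(points)), k):
        radius = dm[:, list(subset)].min(axis=1).max()
        best = min(best, radius)
    return float(best)


def welch_power_equal_var(delta: float, sigma: float, n1: int, n2: int, alpha: float) -> float:
    """Closed-form power of the two-sided two-sample t-test.

    Equal variances, so Welch coincides with the pooled test; noncentral-t
    formula.
    """
    from scipy import stats

    nu = n1 + n2 - 2
    ncp = delta / (sigma * np.sqrt(1.0 / n1 + 1.0 / n2))
    tcrit = stats.t.ppf(1 - alpha / 2, nu)
    return float(
        1 - stats.nct.cdf(tcrit, nu, ncp) + stats.nct.cdf(-tcrit, nu, ncp)
    )
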