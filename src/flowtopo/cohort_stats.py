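"""Cohort-level comparison of PT curves and a clustering sanity check."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .fcs_io import PointCloud
from .topo_features import PTCurve

__all__ = ["CohortComparison", "compare_pt_curves", "cluster_count_check"]


@dataclass
class CohortComparison:
    """Per-threshold Welch t-test of R vs NR PT curves."""

    thresholds: np.ndarray
    nr_mean: np.ndarray
    nr_std: np.ndarray
    r_mean: np.ndarray
    r_std: np.ndarray
    p_values: np.ndarray  # on counts
    p_values_pct: np.ndarray  # on percentages
    n_nr: int
    n_r: int
    alpha: float
    degenerate: np.ndarray  # zero variance in both groups at this tau
    marker_pair: tuple[str, str] | None = None
    dimension: int | None = None

    @property
    def significant(self) -> bool:
        """Whole stated range significant: every tau has p < alpha."""
        return bool(np.all(self.p_values < self.alpha))

    @property
    def pointwise_significant(self) -> np.ndarray:
        return self.p_values < self.alpha


def _welch_per_tau(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Welch t-test per column; degenerate (both zero variance) guarded.

    Identical constant groups give p = 1; separated constant groups p -> 0
    (flagged degenerate either way).
    """
    n_tau = a.shape[1]
    p = np.empty(n_tau)
    degen = np.zeros(n_tau, bool)
    for t in range(n_tau):
        x, y = a[:, t], b[:, t]
        if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
            degen[t] = True
            p[t] = 1.0 if x.mean() == y.mean() else 0.0
        else:
            p[t] = stats.ttest_ind(x, y, equal_var=False).pvalue
    return p, degen


def compare_pt_curves(
    nr: list[PTCurve],
    r: list[PTCurve],
    alpha: float = 0.05,
    marker_pair: tuple[str, str] | None = None,
    dimension: int | None = None,
    bh_correction: bool = False,
) -> CohortComparison:
    """Welch two-sample t-test of R vs NR curves at every threshold.

    Tests counts and percentages separately.  No multiple-testing
    correction by default (matching the reference presentation); pass
    ``bh_correction=True`` for Benjamini-Hochberg adjusted p-values.
    """
    if len(nr) < 2 or len(r) < 2:
        raise ValueError("need at least 2 patients per group")
    grid = nr[0].thresholds
    for c in list(nr) + list(r):
        if not nr[0].same_grid(c):
            raise ValueError("PT curves have mismatching tau grids")
    nr_counts = np.array([c.counts for c in nr])
    r_counts = np.array([c.counts for c in r])
    nr_pct = np.array([c.percentages for c in nr])
    r_pct = np.array([c.percentages for c in r])

    p_counts, degen = _welch_per_tau(nr_counts, r_counts)
    p_pct, _ = _welch_per_tau(nr_pct, r_pct)
    if bh_correction:
        p_counts = _benjamini_hochberg(p_counts)
        p_pct = _benjamini_hochberg(p_pct)
    return CohortComparison(
        thresholds=grid.copy(),
        nr_mean=nr_counts.mean(axis=0),
        nr_std=nr_counts.std(axis=0, ddof=1),
        r_mean=r_counts.mean(axis=0),
        r_std=r_counts.std(axis=0, ddof=1),
        p_values=p_counts,
        p_values_pct=p_pct,
        n_nr=len(nr),
        n_r=len(r),
        alpha=alpha,
        degenerate=degen,
        marker_pair=marker_pair,
        dimension=dimension,
    )


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        idx = order[rank]
        running = min(running, p[idx] * m / (rank + 1))
        adj[idx] = running
    return adj


def cluster_count_check(
    clouds: list[PointCloud],
    k_range: tuple[int, int] = (2, 8),
    seed: int = 0,
    max_cells: int = 2000,
) -> np.ndarray:
    """Per-patient cluster counts by silhouette-selected k-means.

    A generic stand-in for self-organising-map clustering: for each cloud,
    fit k-means over k in [k_lo, k_hi] and report the k with the best
    silhouette score.  Deterministic given ``seed``.
    """
    k_lo, k_hi = k_range
    if k_lo < 2 or k_hi < k_lo:
        raise ValueError(f"invalid k range {k_range}: need 2 <= k_lo <= k_hi")
    counts = np.empty(len(clouds), dtype=int)
    for ci, cloud in enumerate(clouds):
        X = cloud.values
        if len(X) > max_cells:
            rng = np.random.default_rng(seed + ci)
            X = X[np.sort(rng.choice(len(X), max_cells, replace=False))]
        best_k, best_score = k_lo, -np.inf
        for k in range(k_lo, k_hi + 1):
            if k >= len(X):
                break
            km = KMeans(n_clusters=k, n_init=5, random_state=seed).fit(X)
            if len(np.unique(km.labels_)) < 2:
                continue
            score = silhouette_score(X, km.labels_)
            if score > best_score:
                best_k, best_score = k, score
        counts[ci] = best_k
    return counts
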