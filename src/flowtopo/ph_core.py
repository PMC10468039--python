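"""Vietoris-Rips persistent homology in dimensions 0, 1 and 2.

A simplex enters the filtration at its largest pairwise distance.  Pairing
follows the standard boundary-matrix column reduction over Z/2 with
simplices ordered by (filtration value, dimension, lexicographic vertex
order); the implementation uses the equivalent anti-transpose reduction
(see :mod:`flowtopo._reduction`).  Zero-persistence pairs are dropped at
source.  Dimension 0 keeps its single infinite bar; downstream summaries
exclude it.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy.spatial.distance import pdist, squareform

from . import _reduction
from .fcs_io import PointCloud

DEFAULT_SIMPLEX_BUDGET = 20_000_000

__all__ = [
    "DistanceMatrix",
    "Barcode",
    "distance_matrix",
    "persistence_dim0",
    "persistence_vr",
    "enclosing_radius",
    "DEFAULT_SIMPLEX_BUDGET",
]


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise Euclidean distances."""

    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.ascontiguousarray(self.d, dtype=float)
        if self.d.ndim != 2 or self.d.shape[0] != self.d.shape[1]:
            raise ValueError("distance matrix must be square")
        if self.d.shape[0] < 1:
            raise ValueError("distance matrix must have at least one point")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix must have zero diagonal")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return self.d.shape[0]


@dataclass
class Barcode:
    """Intervals [birth, death) of one homology dimension.

    ``bars`` is an (n, 2) array; death may be ``inf`` (dimension 0 only).
    """

    dim: int
    bars: np.ndarray

    def __post_init__(self) -> None:
        self.bars = np.asarray(self.bars, dtype=float).reshape(-1, 2)
        if len(self.bars):
            if np.any(self.bars[:, 0] < 0):
                raise ValueError("births must be non-negative")
            if np.any(self.bars[:, 0] >= self.bars[:, 1]):
                raise ValueError("bars must satisfy birth < death")

    @property
    def finite_bars(self) -> np.ndarray:
        """Bars with finite death (the infinite dim-0 bar excluded)."""
        if not len(self.bars):
            return self.bars
        return self.bars[np.isfinite(self.bars[:, 1])]

    @property
    def persistences(self) -> np.ndarray:
        """Finite bar lengths death - birth."""
        fb = self.finite_bars
        return fb[:, 1] - fb[:, 0] if len(fb) else np.empty(0)

    def __len__(self) -> int:
        return len(self.bars)


def distance_matrix(cloud: PointCloud) -> DistanceMatrix:
    """Exact pairwise Euclidean distances between the cloud's rows."""
    if cloud.n_cells < 1:
        raise ValueError("cannot build a distance matrix from an empty cloud")
    if cloud.n_cells == 1:
        return DistanceMatrix(np.zeros((1, 1)))
    return DistanceMatrix(squareform(pdist(cloud.values, metric="euclidean")))


def enclosing_radius(dm: DistanceMatrix) -> float:
    """min over points of the max distance to any other point.

    Beyond this radius the complex is a cone, hence acyclic in dimensions
    >= 1; truncating the filtration there is exact.
    """
    return float(dm.d.max(axis=1).min())


def persistence_dim0(dm: DistanceMatrix) -> Barcode:
    """Dimension-0 barcode: bars [0, w) for MST edge weights w, plus [0, inf).

    Zero-weight merges (duplicate points) are dropped as zero-persistence.
    """
    n = dm.n
    if n == 1:
        return Barcode(dim=0, bars=np.array([[0.0, np.inf]]))
    weights, _ = _reduction.mst_prim(n, dm.d)
    weights = weights[weights > 0]
    bars = np.empty((len(weights) + 1, 2))
    bars[:-1, 0] = 0.0
    bars[:-1, 1] = np.sort(weights)
    bars[-1] = (0.0, np.inf)
    return Barcode(dim=0, bars=bars)


def persistence_vr(
    dm: DistanceMatrix,
    maxdim: int = 1,
    budget: int = DEFAULT_SIMPLEX_BUDGET,
) -> list[Barcode]:
    """Barcodes of the Vietoris-Rips filtration up to ``maxdim``.

    Parameters
    ----------
    dm : DistanceMatrix
    maxdim : {1, 2}
        Highest homology dimension computed.
    budget : int
        Guard on the top simplex count C(n, maxdim + 2); exceeding it
        raises instead of silently degrading.  Reduce landmarks (the
        paper-style remedy) or raise the budget.
    """
    if maxdim not in (1, 2):
        raise ValueError("maxdim must be 1 or 2")
    n = dm.n
    if comb(n, maxdim + 2) > budget:
        raise ValueError(
            f"simplex budget exceeded: C({n}, {maxdim + 2}) = "
            f"{comb(n, maxdim + 2)} > {budget}; reduce the number of "
            "landmarks or raise the budget"
        )
    barcodes = [persistence_dim0(dm)]
    if n < 3:
        barcodes.append(Barcode(dim=1, bars=np.empty((0, 2))))
        if maxdim == 2:
            barcodes.append(Barcode(dim=2, bars=np.empty((0, 2))))
        return barcodes

    thresh = enclosing_radius(dm)
    _, mst_keys = _reduction.mst_prim(n, dm.d)
    b1, d1, paired_tris = _reduction.pairs_dim1(n, dm.d, thresh, mst_keys)
    order = np.lexsort((d1, b1))
    barcodes.append(Barcode(dim=1, bars=np.column_stack([b1, d1])[order]))
    if maxdim == 2:
        if n < 4:
            barcodes.append(Barcode(dim=2, bars=np.empty((0, 2))))
        else:
            b2, d2 = _reduction.pairs_dim2(n, dm.d, thresh, paired_tris)
            order = np.lexsort((d2, b2))
            barcodes.append(Barcode(dim=2, bars=np.column_stack([b2, d2])[order]))
    return barcodes
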