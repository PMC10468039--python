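"""Barcode summaries: descriptor vectors, PT curves, persistence images.

All summaries operate on finite bars only; the infinite dimension-0 bar is
excluded before anything here is computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .ph_core import Barcode

PI_GRID_SIZES = (5, 10, 25, 50, 100)
PI_SPREADS = (0.01, 0.05)

#: threshold ranges studied per homology dimension (medium, long scales)
PT_RANGES = {
    0: ((0.03, 0.07), (0.1, 0.18)),
    1: ((0.007, 0.015), (0.04, 0.05)),
}
DEFAULT_PT_POINTS = 20

__all__ = [
    "DescriptorVector",
    "PTCurve",
    "PersistenceImage",
    "descriptor_vector",
    "pt_curve",
    "mean_pt_curve",
    "persistence_image",
    "pi_feature",
    "PI_GRID_SIZES",
    "PI_SPREADS",
    "PT_RANGES",
    "DEFAULT_PT_POINTS",
]


@dataclass
class DescriptorVector:
    """Max/min/mean/std of bar persistence, dimensions 0 then 1 (8 reals).

    The std is the population standard deviation (divide by n).  An empty
    barcode contributes an all-zero block.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float).reshape(8)

    def block(self, dim: int) -> np.ndarray:
        return self.values[4 * dim : 4 * dim + 4]


@dataclass
class PTCurve:
    """Counts/percentages of bars persisting strictly longer than each tau."""

    thresholds: np.ndarray
    counts: np.ndarray
    percentages: np.ndarray

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, float)
        self.counts = np.asarray(self.counts, float)
        self.percentages = np.asarray(self.percentages, float)
        if not (len(self.thresholds) == len(self.counts) == len(self.percentages)):
            raise ValueError("threshold/count/percentage lengths differ")

    def same_grid(self, other: "PTCurve") -> bool:
        return self.thresholds.shape == other.thresholds.shape and np.array_equal(
            self.thresholds, other.thresholds
        )


@dataclass
class PersistenceImage:
    """Gaussian-smoothed, persistence-weighted bar mass on a fixed grid.

    Coordinates are (birth, persistence).  Each bar contributes
    w(p) = p / p_max_domain times a bivariate isotropic Gaussian (sigma =
    ``spread``) integrated exactly over each pixel via 1-D CDF differences.
    """

    grid_size: int
    spread: float
    domain: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 1.0), (0.0, 1.0))
    pixels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.pixels is None:
            self.pixels = np.zeros((self.grid_size, self.grid_size))
        self.pixels = np.asarray(self.pixels, float)
        if self.pixels.shape != (self.grid_size, self.grid_size):
            raise ValueError("pixel matrix does not match grid size")

    def same_hyperparameters(self, other: "PersistenceImage") -> bool:
        return (
            self.grid_size == other.grid_size
            and self.spread == other.spread
            and self.domain == other.domain
        )


def descriptor_vector(dim0: Barcode, dim1: Barcode) -> DescriptorVector:
    """8-dimensional topological feature vector for one patient."""
    out = np.zeros(8)
    for k, bc in enumerate((dim0, dim1)):
        pers = bc.persistences
        if len(pers) == 0:
            warnings.warn(
                f"empty dimension-{bc.dim} barcode: descriptor block is zero",
                stacklevel=2,
            )
            continue
        out[4 * k : 4 * k + 4] = (
            pers.max(),
            pers.min(),
            pers.mean(),
            pers.std(),  # population std
        )
    return DescriptorVector(out)


def pt_curve(
    barcode: Barcode,
    tau_range: tuple[float, float],
    n_points: int = DEFAULT_PT_POINTS,
) -> PTCurve:
    """Count (and fraction) of bars with persistence > tau on an even grid.

    Strict inequality; endpoints inclusive.  Percentages use the barcode's
    finite-bar total as denominator and are 0 for an empty barcode.
    """
    lo, hi = tau_range
    if lo >= hi:
        raise ValueError(f"invalid tau range [{lo}, {hi}]: need lo < hi")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    taus = np.linspace(lo, hi, n_points)
    pers = barcode.persistences
    total = len(pers)
    counts = (pers[None, :] > taus[:, None]).sum(axis=1).astype(float)
    percentages = counts / total if total else np.zeros_like(counts)
    return PTCurve(thresholds=taus, counts=counts, percentages=percentages)


def mean_pt_curve(curves: list[PTCurve]) -> PTCurve:
    """Pointwise arithmetic mean of curves sharing one tau grid."""
    if not curves:
        raise ValueError("need at least one curve")
    first = curves[0]
    for c in curves[1:]:
        if not first.same_grid(c):
            raise ValueError("PT curves have mismatching tau grids")
    return PTCurve(
        thresholds=first.thresholds.copy(),
        counts=np.mean([c.counts for c in curves], axis=0),
        percentages=np.mean([c.percentages for c in curves], axis=0),
    )


def persistence_image(
    barcode: Barcode,
    grid_size: int = 25,
    spread: float = 0.05,
    domain: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 1.0), (0.0, 1.0)),
) -> PersistenceImage:
    """Persistence image of a barcode in (birth, persistence) coordinates.

    Pixel (i, j) covers birth bin i (rows) x persistence bin j (columns);
    each bar's Gaussian mass is integrated exactly over every pixel, so the
    image is additive in bars and an empty barcode yields a zero matrix.
    """
    if spread <= 0:
        raise ValueError("spread must be positive")
    if grid_size < 1:
        raise ValueError("grid size must be >= 1")
    (b_lo, b_hi), (p_lo, p_hi) = domain
    if b_lo >= b_hi or p_lo >= p_hi:
        raise ValueError("domain ranges must be non-degenerate")
    img = np.zeros((grid_size, grid_size))
    fb = barcode.finite_bars
    if len(fb) == 0:
        return PersistenceImage(grid_size, spread, domain, img)
    births = fb[:, 0]
    pers = fb[:, 1] - fb[:, 0]
    weights = pers / p_hi  # linear weight, vanishing at zero persistence
    b_edges = np.linspace(b_lo, b_hi, grid_size + 1)
    p_edges = np.linspace(p_lo, p_hi, grid_size + 1)
    # product of 1-D Gaussian CDF differences, one factor per axis
    cdf_b = norm.cdf((b_edges[None, :] - births[:, None]) / spread)
    cdf_p = norm.cdf((p_edges[None, :] - pers[:, None]) / spread)
    mass_b = np.diff(cdf_b, axis=1)  # (bars, grid)
    mass_p = np.diff(cdf_p, axis=1)
    img = np.einsum("k,ki,kj->ij", weights, mass_b, mass_p)
    return PersistenceImage(grid_size, spread, domain, img)


def pi_feature(images: list[PersistenceImage]) -> np.ndarray:
    """Row-major flattening and concatenation of PIs (dim 0 || 1 || 2)."""
    if not images:
        raise ValueError("need at least one image")
    first = images[0]
    for im in images[1:]:
        if not first.same_hyperparameters(im):
            raise ValueError("persistence images have mismatching hyperparameters")
    return np.concatenate([im.pixels.ravel(order="C") for im in images])
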