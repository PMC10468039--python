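"""Raw cloud -> analysis-ready landmark cloud.

Fixed pipeline order: quantile rescale -> CD19 gate -> uniform subsample ->
max-min landmark selection.  Pairwise marker projections are extracted from
the landmark cloud for the per-plane persistence runs.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .fcs_io import PointCloud

logger = logging.getLogger(__name__)

#: markers describing cell geometry, never used in persistence analysis
GEOMETRIC_MARKERS = ("FSC-A", "SSC-A")

DEFAULT_CD19_THRESHOLD = 0.5

__all__ = [
    "RescaleParams",
    "LandmarkSet",
    "quantile_rescale",
    "apply_rescale",
    "gate_cd19",
    "subsample",
    "maxmin_landmarks",
    "project_pair",
    "marker_pairs",
    "ph_markers",
    "GEOMETRIC_MARKERS",
    "DEFAULT_CD19_THRESHOLD",
]


@dataclass
class RescaleParams:
    """Per-marker 0.001/0.999 quantiles used by the affine rescale.

    Quantiles follow the linear-interpolation rule between order statistics
    (numpy's default, "type 7").
    """

    markers: list[str]
    q_low: np.ndarray
    q_high: np.ndarray
    quantile_rule: str = "linear"

    def __post_init__(self) -> None:
        self.q_low = np.asarray(self.q_low, float)
        self.q_high = np.asarray(self.q_high, float)
        bad = np.where(self.q_high <= self.q_low)[0]
        if bad.size:
            names = [self.markers[i] for i in bad]
            raise ValueError(f"degenerate marker(s) {names}: q_high <= q_low")

    def to_dict(self) -> dict:
        return {
            "markers": list(self.markers),
            "q_low": self.q_low.tolist(),
            "q_high": self.q_high.tolist(),
            "quantile_rule": self.quantile_rule,
            "quantiles": [0.001, 0.999],
        }


@dataclass
class LandmarkSet:
    """Row indices chosen by greedy farthest-point (max-min) sampling."""

    indices: np.ndarray
    covering_radius: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("landmark indices must be unique")
        if self.covering_radius < 0:
            raise ValueError("covering radius must be non-negative")

    def __len__(self) -> int:
        return len(self.indices)


def quantile_rescale(cloud: PointCloud) -> tuple[PointCloud, RescaleParams]:
    """Affinely map each marker so its 0.001/0.999 quantiles land on 0/1.

    x' = (x - x_q0.001) / (x_q0.999 - x_q0.001), per marker.  Values are
    deliberately not clipped: points beyond the quantiles map outside
    [0, 1], preserving the cloud's geometry.
    """
    if cloud.n_cells < 2:
        raise ValueError("need at least 2 cells to estimate quantiles")
    q_low = np.quantile(cloud.values, 0.001, axis=0, method="linear")
    q_high = np.quantile(cloud.values, 0.999, axis=0, method="linear")
    degenerate = np.where(q_high <= q_low)[0]
    if degenerate.size:
        names = [cloud.markers[i] for i in degenerate]
        raise ValueError(f"degenerate marker(s) {names}: 0.001/0.999 quantiles coincide")
    params = RescaleParams(markers=list(cloud.markers), q_low=q_low, q_high=q_high)
    return apply_rescale(cloud, params), params


def apply_rescale(cloud: PointCloud, params: RescaleParams) -> PointCloud:
    """Apply previously fitted :class:`RescaleParams` to a cloud."""
    if list(cloud.markers) != list(params.markers):
        raise ValueError("marker list mismatch between cloud and rescale params")
    values = (cloud.values - params.q_low) / (params.q_high - params.q_low)
    return PointCloud(cloud.patient_id, list(cloud.markers), values)


def gate_cd19(
    cloud: PointCloud,
    threshold: float = DEFAULT_CD19_THRESHOLD,
    marker: str = "CD19",
) -> PointCloud:
    """Keep cells whose CD19 intensity is >= threshold (B-cell selection).

    The default threshold of 0.5 on rescaled intensity is a documented
    placeholder; a warning is emitted when it is used implicitly.
    """
    if marker not in cloud.markers:
        raise ValueError(f"marker {marker!r} absent; cannot gate")
    if threshold == DEFAULT_CD19_THRESHOLD:
        warnings.warn(
            "using the default CD19 gate threshold 0.5 (placeholder; "
            "tune to your panel)",
            stacklevel=2,
        )
    keep = cloud.column(marker) >= threshold
    n_kept = int(keep.sum())
    if n_kept == 0:
        raise ValueError(f"no cells pass the {marker} >= {threshold} gate")
    logger.info(
        "%s: %s gate retained %d/%d cells (%.1f%%)",
        cloud.patient_id, marker, n_kept, cloud.n_cells,
        100.0 * n_kept / cloud.n_cells,
    )
    return PointCloud(cloud.patient_id, list(cloud.markers), cloud.values[keep])


def subsample(cloud: PointCloud, n: int, seed: int) -> PointCloud:
    """Uniform subsample without replacement; identity when n >= n_cells."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n >= cloud.n_cells:
        return cloud
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(cloud.n_cells, size=n, replace=False))
    return PointCloud(cloud.patient_id, list(cloud.markers), cloud.values[idx])


def maxmin_landmarks(
    cloud: PointCloud,
    k: int,
    start: int | None = 0,
    seed: int | None = None,
    markers: list[str] | None = None,
) -> LandmarkSet:
    """Greedy farthest-point (max-min) landmark selection.

    Starting from ``start`` (or a seeded random row when ``seed`` is given
    and ``start`` is None), repeatedly add the point maximising its minimum
    Euclidean distance to the chosen set; ties break to the lowest row
    index.  Returns the chosen indices plus the covering radius (max over
    all points of the distance to the nearest landmark).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > cloud.n_cells:
        raise ValueError(f"k={k} exceeds cloud size {cloud.n_cells}")
    if markers is not None:
        cols = [cloud.marker_index(m) for m in markers]
        X = cloud.values[:, cols]
    else:
        X = cloud.values
    n = X.shape[0]
    if start is None:
        rng = np.random.default_rng(seed)
        start = int(rng.integers(n))
    if not (0 <= start < n):
        raise ValueError(f"start index {start} out of range")

    chosen = np.empty(k, dtype=int)
    chosen[0] = start
    mind = cdist(X, X[start : start + 1]).ravel()
    for i in range(1, k):
        # argmax picks the lowest index on ties
        nxt = int(np.argmax(mind))
        chosen[i] = nxt
        d_new = cdist(X, X[nxt : nxt + 1]).ravel()
        np.minimum(mind, d_new, out=mind)
    return LandmarkSet(indices=chosen, covering_radius=float(mind.max()))


def project_pair(cloud: PointCloud, m1: str, m2: str) -> PointCloud:
    """2-column projection of the cloud onto two named markers."""
    for m in (m1, m2):
        if m not in cloud.markers:
            raise ValueError(f"unknown marker {m!r} (cloud has {cloud.markers})")
    cols = [cloud.marker_index(m1), cloud.marker_index(m2)]
    return PointCloud(cloud.patient_id, [m1, m2], cloud.values[:, cols])


def marker_pairs(markers: list[str]) -> list[tuple[str, str]]:
    """All 2-subsets of a marker list in deterministic sorted order."""
    return list(itertools.combinations(sorted(markers), 2))


def ph_markers(markers: list[str]) -> list[str]:
    """Markers eligible for persistence analysis (geometric ones removed)."""
    return [m for m in markers if m not in GEOMETRIC_MARKERS]
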