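"""Labelled synthetic cohorts with a relapse-like topological contrast.

Relapse-like (R) patients get a persistent annulus in the CD10-CD20 plane
and more isolated Gaussian clusters; non-relapse (NR) patients get fewer
clusters and only a narrow annulus in CD38-CD45.  This encodes, in a fully
controlled generator, the qualitative cohort contrast the analysis layers
are meant to detect: more and more-persistent loops and more clusters for
R clouds in planes involving CD10/CD20.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .fcs_io import CohortManifest, ManifestEntry, PointCloud, save_manifest, write_csv_cloud

__all__ = ["RingSpec", "GeneratorSpec", "generate_patient", "generate_cohort", "write_cohort"]


@dataclass(frozen=True)
class RingSpec:
    """An annulus embedded in a named 2-marker plane."""

    plane: tuple[str, str]
    center: tuple[float, float] = (0.5, 0.5)
    radius: float = 0.28
    sigma: float = 0.02  # radial noise

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("ring radius must be positive")
        for c in self.center:
            if not (0.0 <= c - self.radius and c + self.radius <= 1.0):
                raise ValueError(
                    f"ring (center {self.center}, radius {self.radius}) does not "
                    "fit in the [0,1] marker domain"
                )


@dataclass
class GeneratorSpec:
    markers: tuple[str, ...] = ("CD10", "CD20", "CD38", "CD45", "CD19")
    n_cells: int = 2000
    cluster_counts: dict = field(
        default_factory=lambda: {"NR": (1, 2), "R": (3, 5)}
    )
    rings: dict = field(
        default_factory=lambda: {
            "NR": [RingSpec(plane=("CD38", "CD45"), center=(0.5, 0.55), radius=0.12, sigma=0.02)],
            "R": [RingSpec(plane=("CD10", "CD20"), center=(0.5, 0.5), radius=0.28, sigma=0.02)],
        }
    )
    ring_fraction: float = 0.45
    blob_sigma: float = 0.04
    noise_fraction: float = 0.02
    b_cell_fraction: float = 0.9
    center_jitter: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.noise_fraction < 1.0):
            raise ValueError("noise fraction must be in [0, 1)")
        if not (0.0 < self.b_cell_fraction <= 1.0):
            raise ValueError("b_cell_fraction must be in (0, 1]")
        if not (0.0 <= self.ring_fraction <= 1.0):
            raise ValueError("ring_fraction must be in [0, 1]")
        for lo, hi in self.cluster_counts.values():
            if lo < 1 or hi < lo:
                raise ValueError("cluster count range must satisfy 1 <= lo <= hi")
        if "CD19" not in self.markers:
            raise ValueError("generator requires a CD19 column for gating")
        for label, rings in self.rings.items():
            for ring in rings:
                for m in ring.plane:
                    if m not in self.markers:
                        raise ValueError(f"ring plane marker {m!r} not in panel")

    def to_dict(self) -> dict:
        return {
            "markers": list(self.markers),
            "n_cells": self.n_cells,
            "cluster_counts": {k: list(v) for k, v in self.cluster_counts.items()},
            "rings": {
                label: [
                    {
                        "plane": list(r.plane),
                        "center": list(r.center),
                        "radius": r.radius,
                        "sigma": r.sigma,
                    }
                    for r in rings
                ]
                for label, rings in self.rings.items()
            },
            "ring_fraction": self.ring_fraction,
            "blob_sigma": self.blob_sigma,
            "noise_fraction": self.noise_fraction,
            "b_cell_fraction": self.b_cell_fraction,
            "center_jitter": self.center_jitter,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorSpec":
        data = dict(data)
        data["markers"] = tuple(data.get("markers", cls().markers))
        if "cluster_counts" in data:
            data["cluster_counts"] = {
                k: tuple(v) for k, v in data["cluster_counts"].items()
            }
        if "rings" in data:
            data["rings"] = {
                label: [
                    RingSpec(
                        plane=tuple(r["plane"]),
                        center=tuple(r.get("center", (0.5, 0.5))),
                        radius=r.get("radius", 0.28),
                        sigma=r.get("sigma", 0.02),
                    )
                    for r in rings
                ]
                for label, rings in data["rings"].items()
            }
        return cls(**data)


def _structural_markers(spec: GeneratorSpec) -> list[str]:
    return [m for m in spec.markers if m != "CD19"]


def generate_patient(spec: GeneratorSpec, label: str, seed: int) -> PointCloud:
    """One patient cloud: Gaussian blobs + per-label annuli, CD19-gated mix.

    Deterministic given (spec, label, seed); all values clipped to [0, 1].
    """
    if label not in ("R", "NR"):
        raise ValueError(f"label must be R or NR, got {label!r}")
    rng = np.random.default_rng(seed)
    struct = _structural_markers(spec)
    d = len(struct)
    col = {m: i for i, m in enumerate(struct)}

    n_noise = int(round(spec.n_cells * spec.noise_fraction))
    n_rest = spec.n_cells - n_noise
    n_b = int(round(n_rest * spec.b_cell_fraction))
    n_contam = n_rest - n_b

    rings = list(spec.rings.get(label, []))
    n_ring_total = int(round(n_b * spec.ring_fraction)) if rings else 0
    n_blob_total = n_b - n_ring_total

    # jittered ring geometry for this patient
    placed_rings = []
    for ring in rings:
        for _ in range(100):
            cx = ring.center[0] + rng.uniform(-spec.center_jitter, spec.center_jitter)
            cy = ring.center[1] + rng.uniform(-spec.center_jitter, spec.center_jitter)
            rr = ring.radius * rng.uniform(0.9, 1.1)
            if 0 <= cx - rr and cx + rr <= 1 and 0 <= cy - rr and cy + rr <= 1:
                placed_rings.append(replace(ring, center=(cx, cy), radius=rr))
                break
        else:  # pragma: no cover - jitter never exhausts 100 tries
            placed_rings.append(ring)

    def blocked(center_vec: np.ndarray) -> bool:
        # keep blob centres out of ring interiors in their own planes
        for ring in placed_rings:
            i1, i2 = col[ring.plane[0]], col[ring.plane[1]]
            dist = np.hypot(center_vec[i1] - ring.center[0], center_vec[i2] - ring.center[1])
            if dist < ring.radius + 0.08:
                return True
        return False

    lo, hi = spec.cluster_counts[label]
    n_blobs = int(rng.integers(lo, hi + 1))
    centers = []
    while len(centers) < n_blobs:
        c = rng.uniform(0.15, 0.85, size=d)
        if not blocked(c):
            centers.append(c)

    chunks = []
    # blobs
    sizes = np.full(n_blobs, n_blob_total // n_blobs)
    sizes[: n_blob_total % n_blobs] += 1
    for c, sz in zip(centers, sizes):
        chunks.append(rng.normal(c, spec.blob_sigma, size=(sz, d)))
    # rings
    if placed_rings and n_ring_total:
        rsizes = np.full(len(placed_rings), n_ring_total // len(placed_rings))
        rsizes[: n_ring_total % len(placed_rings)] += 1
        for ring, sz in zip(placed_rings, rsizes):
            theta = rng.uniform(0, 2 * np.pi, sz)
            radius = ring.radius + rng.normal(0, ring.sigma, sz)
            block = np.empty((sz, d))
            off_center = rng.uniform(0.25, 0.75, size=d)
            for i, m in enumerate(struct):
                block[:, i] = rng.normal(off_center[i], spec.blob_sigma, sz)
            i1, i2 = col[ring.plane[0]], col[ring.plane[1]]
            block[:, i1] = ring.center[0] + radius * np.cos(theta)
            block[:, i2] = ring.center[1] + radius * np.sin(theta)
            chunks.append(block)
    X_b = np.vstack(chunks) if chunks else np.empty((0, d))
    cd19_b = rng.normal(0.8, 0.06, len(X_b))

    # contaminant (non-B) cells: below the gate
    X_c = rng.uniform(0.0, 1.0, size=(n_contam, d))
    cd19_c = np.abs(rng.normal(0.15, 0.08, n_contam))

    # background noise: anywhere, any CD19
    X_n = rng.uniform(0.0, 1.0, size=(n_noise, d))
    cd19_n = rng.uniform(0.0, 1.0, n_noise)

    X = np.vstack([X_b, X_c, X_n])
    cd19 = np.concatenate([cd19_b, cd19_c, cd19_n])
    values = np.empty((spec.n_cells, len(spec.markers)))
    for i, m in enumerate(spec.markers):
        values[:, i] = cd19 if m == "CD19" else X[:, col[m]]
    np.clip(values, 0.0, 1.0, out=values)
    perm = rng.permutation(spec.n_cells)
    return PointCloud(patient_id=f"synthetic-{label}-{seed}", markers=list(spec.markers), values=values[perm])


def _risk_group(label: str, u: float) -> str:
    # ~85% of relapsing patients present as low/intermediate risk
    if label == "R":
        if u < 0.45:
            return "low"
        if u < 0.85:
            return "intermediate"
        return "high"
    if u < 0.5:
        return "low"
    if u < 0.8:
        return "intermediate"
    return "high"


def generate_cohort(
    spec: GeneratorSpec,
    n_nr: int = 80,
    n_r: int = 16,
    master_seed: int = 0,
    discovery_fraction: float = 0.6,
) -> tuple[CohortManifest, dict[str, PointCloud]]:
    """A labelled cohort with per-patient child seeds from the master seed.

    Returns the manifest (ids, labels, synthetic risk groups, a stratified
    discovery/validation split, placeholder paths) and the clouds keyed by
    patient id.
    """
    if n_nr < 1 or n_r < 1:
        raise ValueError("need at least one patient per class")
    ss = np.random.SeedSequence(master_seed)
    child_seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(n_nr + n_r + 1)]
    risk_rng = np.random.default_rng(child_seeds[-1])

    labels = ["NR"] * n_nr + ["R"] * n_r
    entries = []
    clouds: dict[str, PointCloud] = {}
    counters = {"NR": 0, "R": 0}
    totals = {"NR": n_nr, "R": n_r}
    for i, label in enumerate(labels):
        pid = f"P{i + 1:03d}"
        cloud = generate_patient(spec, label, seed=child_seeds[i])
        cloud.patient_id = pid
        clouds[pid] = cloud
        k = counters[label]
        split = "discovery" if k < round(totals[label] * discovery_fraction) else "validation"
        counters[label] += 1
        entries.append(
            ManifestEntry(
                patient_id=pid,
                label=label,
                risk_group=_risk_group(label, risk_rng.uniform()),
                split=split,
                path=Path(f"{pid}.csv"),
            )
        )
    return CohortManifest(entries), clouds


def write_cohort(
    manifest: CohortManifest,
    clouds: dict[str, PointCloud],
    out_dir: str | Path,
) -> Path:
    """Write per-patient CSV clouds plus the manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for e in manifest:
        path = out_dir / f"{e.patient_id}.csv"
        write_csv_cloud(clouds[e.patient_id], path)
        entries.append(replace(e, path=path))
    manifest_path = out_dir / "manifest.csv"
    updated = CohortManifest(entries)
    save_manifest(updated, manifest_path, relative_to=out_dir)
    return manifest_path
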