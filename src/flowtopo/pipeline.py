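"""End-to-end orchestration of the three prognostic approaches.

* approach 2: per-pair PT curves, cohort mean curves on the discovery
  split, PT-curve-distance relapse scores for held-out patients;
* approach 3: multi-marker persistence images classified with SVM (and
  optionally logistic regression);
* screening: Random-Forest ranking of pairwise marker combinations on
  8-dimensional descriptor vectors.

Both approaches consume identical preprocessing artifacts (rescale ->
CD19 gate -> subsample -> per-marker-group max-min landmarks).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import fcs_io
from .classify import (
    ClassificationReport,
    SVMConfig,
    classification_report,
    lr_classify,
    pt_distance_score,
    rf_screen,
    svm_classify,
)
from .cohort_stats import CohortComparison, compare_pt_curves
from .fcs_io import CohortManifest, PointCloud
from .ph_core import DEFAULT_SIMPLEX_BUDGET, distance_matrix, persistence_vr
from .preprocess import (
    DEFAULT_CD19_THRESHOLD,
    gate_cd19,
    marker_pairs,
    maxmin_landmarks,
    ph_markers,
    quantile_rescale,
    subsample,
)
from .topo_features import (
    PI_GRID_SIZES,
    PI_SPREADS,
    descriptor_vector,
    persistence_image,
    pi_feature,
    pt_curve,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "Approach2Result", "Approach3Result", "run_approach2", "run_approach3", "run_screen"]


@dataclass
class RunConfig:
    """Validated knobs for the pipeline; hash recorded in every output."""

    markers: tuple[str, ...] = ("CD10", "CD20", "CD38", "CD45")
    n_cells: int = 100_000
    n_landmarks: int = 10_000
    n_landmarks_dim2: int = 1_000
    cd19_threshold: float = DEFAULT_CD19_THRESHOLD
    pt_ranges: dict = field(default_factory=lambda: {0: (0.03, 0.07), 1: (0.04, 0.05)})
    n_pt_points: int = 20
    pi_grid: int = 25
    pi_spread: float = 0.05
    pi_dims: tuple[int, ...] = (0, 1)
    svm: SVMConfig = field(default_factory=SVMConfig)
    oversample: bool = True
    subgroup_low_intermediate: bool = False
    budget: int = DEFAULT_SIMPLEX_BUDGET
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pi_grid not in PI_GRID_SIZES:
            raise ValueError(f"pi_grid must be one of {PI_GRID_SIZES}, got {self.pi_grid}")
        if self.pi_spread not in PI_SPREADS:
            raise ValueError(f"pi_spread must be one of {PI_SPREADS}, got {self.pi_spread}")
        if any(d not in (0, 1, 2) for d in self.pi_dims):
            raise ValueError("pi_dims must be drawn from {0, 1, 2}")
        if self.n_landmarks < 2 or self.n_cells < 2:
            raise ValueError("n_cells and n_landmarks must be >= 2")

    @classmethod
    def test_profile(cls, **overrides) -> "RunConfig":
        """Small sizes so the whole pipeline runs in minutes."""
        defaults = dict(n_cells=2000, n_landmarks=200, n_landmarks_dim2=100)
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def paper_profile(cls, **overrides) -> "RunConfig":
        cfg = cls(**overrides)
        warnings.warn(
            "paper-profile sizes (1e5 cells, 1e4 landmarks) imply week-scale "
            "persistence runtimes for full pairwise scans",
            stacklevel=2,
        )
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()
                if not isinstance(v, (SVMConfig, dict))
            }
            | {"pt_ranges": {str(k): list(v) for k, v in self.pt_ranges.items()}},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _patient_seed(config_seed: int, patient_id: str) -> int:
    return (config_seed * 1_000_003 + zlib.crc32(patient_id.encode())) % 2**31


def load_cloud(path: Path, patient_id: str) -> PointCloud:
    if str(path).lower().endswith(".fcs"):
        cloud = fcs_io.read_fcs(path)
        cloud.patient_id = patient_id
        return cloud
    return fcs_io.read_csv_cloud(path, patient_id)


def _prep_patient(cloud: PointCloud, config: RunConfig) -> PointCloud:
    """Shared preprocessing: rescale -> gate -> subsample, PH markers only."""
    for m in list(config.markers) + ["CD19"]:
        if m not in cloud.markers:
            raise ValueError(f"patient {cloud.patient_id}: required marker {m!r} missing")
    rescaled, _ = quantile_rescale(cloud)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gated = gate_cd19(rescaled, config.cd19_threshold)
    sub = subsample(gated, config.n_cells, seed=_patient_seed(config.seed, cloud.patient_id))
    keep = [m for m in ph_markers(list(config.markers)) if m in sub.markers]
    cols = [sub.marker_index(m) for m in keep]
    return PointCloud(sub.patient_id, keep, sub.values[:, cols])


def _landmark_cloud(cloud: PointCloud, k: int, markers: list[str]) -> PointCloud:
    proj = cloud if list(cloud.markers) == markers else PointCloud(
        cloud.patient_id, markers, cloud.values[:, [cloud.marker_index(m) for m in markers]]
    )
    k = min(k, proj.n_cells)
    lm = maxmin_landmarks(proj, k=k, start=0)
    return PointCloud(proj.patient_id, markers, proj.values[lm.indices])


def _patient_pair_curves(
    prepped: PointCloud, config: RunConfig, cache_dir: Path | None
) -> dict[tuple[tuple[str, str], int], "object"]:
    """PT curves for every marker pair and dimension of one patient."""
    curves = {}
    for pair in marker_pairs(ph_markers(list(config.markers))):
        barcodes = None
        cache_file = None
        if cache_dir is not None:
            cache_file = cache_dir / f"{prepped.patient_id}_{pair[0]}_{pair[1]}.barcode.csv"
            if cache_file.exists():
                barcodes = fcs_io.load_barcodes(cache_file)
                logger.info("%s %s: barcode cache hit", prepped.patient_id, pair)
        if barcodes is None:
            lm = _landmark_cloud(prepped, config.n_landmarks, list(pair))
            barcodes = persistence_vr(distance_matrix(lm), maxdim=1, budget=config.budget)
            if cache_file is not None:
                cache_dir.mkdir(parents=True, exist_ok=True)
                fcs_io.save_barcodes(barcodes, cache_file)
        for dim in (0, 1):
            curves[(pair, dim)] = pt_curve(
                barcodes[dim], config.pt_ranges[dim], config.n_pt_points
            )
    return curves


@dataclass
class Approach2Result:
    scores: dict[str, float]  # held-out patient id -> relapse probability
    labels: dict[str, str]
    auc: float | None
    comparisons: list[CohortComparison]
    config_hash: str
    seed: int


@dataclass
class Approach3Result:
    svm: ClassificationReport
    lr: ClassificationReport | None
    lr_coefficients: np.ndarray | None
    patient_ids: list[str]
    n_subgroup_excluded: int
    config_hash: str
    seed: int


def _mean_curves(curve_sets, key):
    from .topo_features import mean_pt_curve

    return mean_pt_curve([c[key] for c in curve_sets])


def run_approach2(
    manifest: CohortManifest,
    config: RunConfig,
    clouds: dict[str, PointCloud] | None = None,
    cache_dir: str | Path | None = None,
) -> Approach2Result:
    """PT-curve distance prognosis on the validation split.

    Cohort mean curves per (marker pair, dimension) are estimated from the
    discovery split; each validation patient is scored by
    :func:`flowtopo.classify.pt_distance_score`.
    """
    cache_dir = Path(cache_dir) if cache_dir is not None else None
    all_curves: dict[str, dict] = {}
    for e in manifest:
        cloud = clouds[e.patient_id] if clouds is not None else load_cloud(e.path, e.patient_id)
        prepped = _prep_patient(cloud, config)
        all_curves[e.patient_id] = _patient_pair_curves(prepped, config, cache_dir)

    disc = manifest.subset(split="discovery")
    nr_ids = [e.patient_id for e in disc if e.label == "NR"]
    r_ids = [e.patient_id for e in disc if e.label == "R"]
    if not nr_ids or not r_ids:
        raise ValueError("discovery split must contain both R and NR patients")
    keys = list(next(iter(all_curves.values())))
    mean_nr = {k: _mean_curves([all_curves[i] for i in nr_ids], k) for k in keys}
    mean_r = {k: _mean_curves([all_curves[i] for i in r_ids], k) for k in keys}

    comparisons = [
        compare_pt_curves(
            [all_curves[i][k] for i in nr_ids],
            [all_curves[i][k] for i in r_ids],
            marker_pair=k[0],
            dimension=k[1],
        )
        for k in keys
        if len(nr_ids) >= 2 and len(r_ids) >= 2
    ]

    val = manifest.subset(split="validation")
    scores = {
        e.patient_id: pt_distance_score(all_curves[e.patient_id], mean_nr, mean_r)
        for e in val
    }
    labels = {e.patient_id: e.label for e in val}
    y = np.array([1 if labels[p] == "R" else 0 for p in scores])
    auc = None
    if len(np.unique(y)) == 2:
        auc = classification_report(
            y, (np.array(list(scores.values())) > 0.5).astype(int), list(scores.values())
        ).auc
    return Approach2Result(
        scores=scores,
        labels=labels,
        auc=auc,
        comparisons=comparisons,
        config_hash=config.config_hash(),
        seed=config.seed,
    )


def run_approach3(
    manifest: CohortManifest,
    config: RunConfig,
    clouds: dict[str, PointCloud] | None = None,
    with_lr: bool = False,
) -> Approach3Result:
    """Persistence-image classification of the multi-marker clouds."""
    entries = list(manifest)
    n_excluded = 0
    if config.subgroup_low_intermediate:
        kept = [e for e in entries if e.risk_group in ("low", "intermediate")]
        n_excluded = len(entries) - len(kept)
        logger.info("subgroup mode: %d patients kept, %d excluded", len(kept), n_excluded)
        entries = kept

    maxdim = max(config.pi_dims) if config.pi_dims else 1
    features = []
    ids = []
    labels = []
    domain = ((0.0, 1.0), (0.0, 1.0))
    group = sorted(ph_markers(list(config.markers)))
    for e in entries:
        cloud = clouds[e.patient_id] if clouds is not None else load_cloud(e.path, e.patient_id)
        prepped = _prep_patient(cloud, config)
        k = config.n_landmarks_dim2 if maxdim == 2 else config.n_landmarks
        lm = _landmark_cloud(prepped, k, group)
        barcodes = persistence_vr(
            distance_matrix(lm), maxdim=max(maxdim, 1), budget=config.budget
        )
        images = [
            persistence_image(barcodes[d], config.pi_grid, config.pi_spread, domain)
            for d in config.pi_dims
        ]
        features.append(pi_feature(images))
        ids.append(e.patient_id)
        labels.append(e.label)
    X = np.vstack(features)
    svm_report = svm_classify(
        X, labels, config.svm, oversample_minority=config.oversample, seed=config.seed
    )
    lr_report = lr_coef = None
    if with_lr:
        lr_report, lr_coef = lr_classify(
            X,
            labels,
            folds=config.svm.folds,
            oversample_minority=config.oversample,
            seed=config.seed,
            coef_shape=(config.pi_grid, config.pi_grid * len(config.pi_dims)),
        )
    return Approach3Result(
        svm=svm_report,
        lr=lr_report,
        lr_coefficients=lr_coef,
        patient_ids=ids,
        n_subgroup_excluded=n_excluded,
        config_hash=config.config_hash(),
        seed=config.seed,
    )


def run_screen(
    manifest: CohortManifest,
    config: RunConfig,
    clouds: dict[str, PointCloud] | None = None,
    panel: list[str] | None = None,
):
    """Descriptor vectors per marker pair -> Random-Forest screening."""
    first = None
    features: dict[tuple[str, str], list[np.ndarray]] = {}
    labels = []
    for e in manifest:
        cloud = clouds[e.patient_id] if clouds is not None else load_cloud(e.path, e.patient_id)
        patient_panel = panel or ph_markers([m for m in cloud.markers if m != "CD19"])
        if first is None:
            first = patient_panel
        elif patient_panel != first:
            raise ValueError(f"patient {e.patient_id}: marker panel mismatch")
        cfg = RunConfig(**{**config.__dict__, "markers": tuple(first) + ("CD19",)}) \
            if "CD19" not in first else config
        prepped = _prep_patient(cloud, cfg)
        labels.append(e.label)
        for pair in marker_pairs(ph_markers(first)):
            lm = _landmark_cloud(prepped, config.n_landmarks, list(pair))
            barcodes = persistence_vr(distance_matrix(lm), maxdim=1, budget=config.budget)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                vec = descriptor_vector(barcodes[0], barcodes[1]).values
            features.setdefault(pair, []).append(vec)
    feature_mats = {pair: np.vstack(v) for pair, v in features.items()}
    return rf_screen(feature_mats, labels, seed=config.seed)
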