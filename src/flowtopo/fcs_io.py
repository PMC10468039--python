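"""Reading and writing of point clouds, barcodes, curves, images and manifests.

Point clouds come either from FCS 3.0 list-mode files or from delimited
text (one row per cell, one column per marker).  Only the FCS 3.0 dialect
needed here is supported: list mode, datatypes ``F`` (float32) and ``D``
(float64).  Analysis segments are ignored.  All derived artifacts
(barcodes, persistence-threshold curves, persistence images) round-trip
through plain comma-delimited text with JSON sidecars for hyperparameters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_LABELS = ("R", "NR")
VALID_RISK_GROUPS = ("low", "intermediate", "high", "unknown")
VALID_SPLITS = ("discovery", "validation")

__all__ = [
    "PointCloud",
    "ManifestEntry",
    "CohortManifest",
    "read_fcs",
    "write_fcs_fixture",
    "read_csv_cloud",
    "write_csv_cloud",
    "load_manifest",
    "save_manifest",
    "save_barcodes",
    "load_barcodes",
    "save_curve",
    "load_curve",
    "save_image",
    "load_image",
]


class FCSFormatError(ValueError):
    """Raised when an FCS file violates the supported FCS 3.0 subset."""


@dataclass
class PointCloud:
    """A patient's cells-by-markers intensity matrix.

    Parameters
    ----------
    patient_id : str
        Identifier of the patient the cloud belongs to.
    markers : list of str
        Ordered, unique marker names, one per column.
    values : ndarray of shape (n_cells, n_markers)
        Real-valued intensities; finite after loading (rows containing
        NaN/Inf are dropped by the readers and counted).
    """

    patient_id: str
    markers: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape[1] != len(self.markers):
            raise ValueError(
                f"marker count {len(self.markers)} does not match "
                f"matrix width {self.values.shape[1]}"
            )
        if len(set(self.markers)) != len(self.markers):
            raise ValueError(f"duplicate marker names: {self.markers}")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def marker_index(self, marker: str) -> int:
        try:
            return self.markers.index(marker)
        except ValueError:
            raise KeyError(
                f"marker {marker!r} not in cloud (has {self.markers})"
            ) from None

    def column(self, marker: str) -> np.ndarray:
        return self.values[:, self.marker_index(marker)]


@dataclass
class ManifestEntry:
    patient_id: str
    label: str
    risk_group: str
    split: str
    path: Path


@dataclass
class CohortManifest:
    """Patient ids, relapse labels, clinical risk groups and dataset splits."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.patient_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient ids in manifest: {dupes}")
        for e in self.entries:
            if e.label not in VALID_LABELS:
                raise ValueError(
                    f"unknown label {e.label!r} for {e.patient_id}; "
                    f"allowed: {list(VALID_LABELS)}"
                )
            if e.risk_group not in VALID_RISK_GROUPS:
                raise ValueError(
                    f"unknown risk group {e.risk_group!r} for {e.patient_id}; "
                    f"allowed: {list(VALID_RISK_GROUPS)}"
                )
            if e.split not in VALID_SPLITS:
                raise ValueError(
                    f"unknown split {e.split!r} for {e.patient_id}; "
                    f"allowed: {list(VALID_SPLITS)}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def subset(self, **criteria) -> "CohortManifest":
        """Entries matching all keyword criteria, e.g. ``label="R"``."""
        kept = [
            e
            for e in self.entries
            if all(getattr(e, k) == v for k, v in criteria.items())
        ]
        return CohortManifest(kept)

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.entries]


# ---------------------------------------------------------------------------
# FCS 3.0
# ---------------------------------------------------------------------------

def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FCSFormatError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    parts = body.split(delim)
    if len(parts) % 2 != 0:
        # trailing empty value is tolerated
        if parts and parts[-1] == b"":
            parts = parts[:-1]
    if len(parts) % 2 != 0:
        raise FCSFormatError("TEXT segment has an odd number of tokens")
    kw: dict[str, str] = {}
    for key, val in zip(parts[0::2], parts[1::2]):
        kw[key.decode("ascii", "replace").strip().upper()] = val.decode(
            "ascii", "replace"
        ).strip()
    return kw


def read_fcs(path: str | Path) -> PointCloud:
    """Read an FCS 3.0 list-mode file into a :class:`PointCloud`.

    Only ``$DATATYPE`` ``F`` (float32) and ``D`` (float64) are supported;
    column names are taken from ``$PnN`` with ``$PnS`` as fallback, and
    ``$BYTEORD`` is honoured.  Rows containing NaN/Inf are dropped and
    counted in the log.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 58:
        raise FCSFormatError(f"{path}: file too short to hold an FCS header")
    version = raw[0:6].decode("ascii", "replace")
    if version != "FCS3.0":
        raise FCSFormatError(f"{path}: unsupported FCS version {version!r}")
    try:
        text_start = int(raw[10:18])
        text_end = int(raw[18:26])
        data_start = int(raw[26:34])
        data_end = int(raw[34:42])
    except ValueError as exc:
        raise FCSFormatError(f"{path}: malformed header offsets") from exc
    kw = _parse_text_segment(raw[text_start : text_end + 1])

    mode = kw.get("$MODE", "")
    if mode != "L":
        raise FCSFormatError(f"{path}: $MODE={mode!r} unsupported (list mode only)")
    datatype = kw.get("$DATATYPE", "")
    if datatype not in ("F", "D"):
        raise FCSFormatError(
            f"{path}: unsupported datatype {datatype!r} (only F and D)"
        )
    try:
        n_par = int(kw["$PAR"])
        n_tot = int(kw["$TOT"])
    except KeyError as exc:
        raise FCSFormatError(f"{path}: missing required keyword {exc}") from exc
    byteord = kw.get("$BYTEORD", "")
    if byteord in ("1,2,3,4", "1,2"):
        endian = "<"
    elif byteord in ("4,3,2,1", "2,1"):
        endian = ">"
    else:
        raise FCSFormatError(f"{path}: unsupported $BYTEORD {byteord!r}")

    itemsize = 4 if datatype == "F" else 8
    for p in range(1, n_par + 1):
        bits = int(kw.get(f"$P{p}B", itemsize * 8))
        if bits != itemsize * 8:
            raise FCSFormatError(
                f"{path}: $P{p}B={bits} inconsistent with datatype {datatype}"
            )

    if data_start == 0 and data_end == 0:
        data_start = int(kw.get("$BEGINDATA", 0))
        data_end = int(kw.get("$ENDDATA", 0))
    expected = n_tot * n_par * itemsize
    available = data_end - data_start + 1 if n_tot > 0 else 0
    if n_tot > 0 and (available < expected or data_end >= len(raw)):
        raise FCSFormatError(
            f"{path}: DATA segment length mismatch "
            f"(need {expected} bytes, segment holds {max(available, 0)})"
        )
    dtype = np.dtype(f"{endian}f{itemsize}")
    if n_tot > 0:
        data = np.frombuffer(
            raw[data_start : data_start + expected], dtype=dtype
        ).reshape(n_tot, n_par)
    else:
        data = np.empty((0, n_par), dtype=dtype)

    names = []
    for p in range(1, n_par + 1):
        name = kw.get(f"$P{p}N") or kw.get(f"$P{p}S") or f"P{p}"
        names.append(name)

    values = np.asarray(data, dtype=float)
    finite = np.isfinite(values).all(axis=1)
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.warning("%s: dropped %d non-finite rows", path, n_dropped)
        values = values[finite]
    return PointCloud(patient_id=path.stem, markers=names, values=values)


def write_fcs_fixture(cloud: PointCloud, path: str | Path) -> None:
    """Write a minimal valid FCS 3.0 file (float32, little-endian, list mode).

    ``read_fcs`` inverts this exactly up to float32 quantisation.
    """
    if cloud.n_markers == 0:
        raise ValueError("cannot write an FCS fixture with an empty marker list")
    if not np.isfinite(cloud.values).all():
        raise ValueError("cloud contains non-finite values")
    path = Path(path)
    n_tot, n_par = cloud.values.shape
    data = np.ascontiguousarray(cloud.values, dtype="<f4").tobytes()

    delim = "/"
    kw: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"),
        ("$ENDSTEXT", "0"),
        ("$BYTEORD", "1,2,3,4"),
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$PAR", str(n_par)),
        ("$TOT", str(n_tot)),
    ]
    for p, name in enumerate(cloud.markers, start=1):
        if delim in name:
            raise ValueError(f"marker name {name!r} contains the delimiter {delim!r}")
        kw.append((f"$P{p}N", name))
        kw.append((f"$P{p}B", "32"))
        kw.append((f"$P{p}E", "0,0"))
        kw.append((f"$P{p}R", "262144"))

    def build_text(begin_data: int, end_data: int) -> bytes:
        items = kw + [("$BEGINDATA", str(begin_data)), ("$ENDDATA", str(end_data))]
        text = delim + delim.join(f"{k}{delim}{v}" for k, v in items) + delim
        return text.encode("ascii")

    header_len = 58
    # two passes: offsets depend on the text length, which depends on offsets
    text = build_text(0, 0)
    for _ in range(3):
        text_start = header_len
        text_end = text_start + len(text) - 1
        data_start = text_end + 1
        data_end = data_start + len(data) - 1 if data else 0
        new_text = build_text(data_start, data_end)
        if len(new_text) == len(text):
            text = new_text
            break
        text = new_text
    else:  # pragma: no cover - converges in <= 2 passes
        raise RuntimeError("could not stabilise FCS offsets")

    text_start = header_len
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + len(data) - 1 if data else 0
    header = b"FCS3.0    " + "".join(
        f"{off:>8d}" for off in (text_start, text_end, data_start, data_end, 0, 0)
    ).encode("ascii")
    assert len(header) == header_len
    path.write_bytes(header + text + data)


# ---------------------------------------------------------------------------
# Delimited-text clouds
# ---------------------------------------------------------------------------

def read_csv_cloud(path: str | Path, patient_id: str | None = None) -> PointCloud:
    """Read a CSV with a marker-name header and one row per cell.

    Rows containing any non-numeric, NaN or infinite cell are dropped and
    the count logged.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
    if not header:
        raise ValueError(f"{path}: empty file")
    names = [c.strip() for c in header.split(",")]
    if len(set(names)) != len(names):
        raise ValueError(f"{path}: duplicate header names {names}")
    df = pd.read_csv(path, header=0, names=names)
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    finite = np.isfinite(values).all(axis=1) if len(values) else np.array([], bool)
    n_dropped = int(len(values) - finite.sum())
    if n_dropped:
        logger.warning("%s: dropped %d non-numeric/non-finite rows", path, n_dropped)
    return PointCloud(
        patient_id=patient_id or path.stem, markers=names, values=values[finite]
    )


def write_csv_cloud(cloud: PointCloud, path: str | Path) -> None:
    pd.DataFrame(cloud.values, columns=cloud.markers).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

def load_manifest(path: str | Path, check_paths: bool = True) -> CohortManifest:
    """Load a cohort manifest CSV (patient_id,label,risk_group,split,path).

    Paths are resolved relative to the manifest's directory and must exist
    unless ``check_paths`` is False.
    """
    path = Path(path)
    df = pd.read_csv(path, header=0, dtype=str)
    required = ["patient_id", "label", "risk_group", "split", "path"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing columns {missing}")
    entries = []
    for row in df.itertuples(index=False):
        p = Path(str(row.path))
        if not p.is_absolute():
            p = path.parent / p
        entries.append(
            ManifestEntry(
                patient_id=str(row.patient_id),
                label=str(row.label),
                risk_group=str(row.risk_group),
                split=str(row.split),
                path=p,
            )
        )
    manifest = CohortManifest(entries)
    if check_paths:
        for e in manifest:
            if not e.path.exists():
                raise FileNotFoundError(
                    f"manifest entry {e.patient_id}: path {e.path} not found"
                )
    return manifest


def save_manifest(
    manifest: CohortManifest, path: str | Path, relative_to: str | Path | None = None
) -> None:
    path = Path(path)
    rows = []
    for e in manifest:
        p = e.path
        if relative_to is not None:
            try:
                p = p.relative_to(relative_to)
            except ValueError:
                pass
        rows.append(
            {
                "patient_id": e.patient_id,
                "label": e.label,
                "risk_group": e.risk_group,
                "split": e.split,
                "path": str(p),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Barcodes / curves / images as plain text
# ---------------------------------------------------------------------------

def save_barcodes(barcodes, path: str | Path) -> None:
    """Persist barcodes as three-column text: dimension,birth,death.

    Infinite deaths are spelled ``inf`` literally.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("dimension,birth,death\n")
        for bc in barcodes:
            for birth, death in bc.bars:
                d = "inf" if np.isinf(death) else repr(float(death))
                fh.write(f"{bc.dim},{float(birth)!r},{d}\n")


def load_barcodes(path: str | Path):
    """Inverse of :func:`save_barcodes`; returns a list of Barcode by dim."""
    from .ph_core import Barcode

    path = Path(path)
    by_dim: dict[int, list[tuple[float, float]]] = {}
    with path.open() as fh:
        header = fh.readline()
        if not header.startswith("dimension"):
            raise ValueError(f"{path}: not a barcode file")
        for line in fh:
            line = line.strip()
            if not line:
                continue
            dim_s, b_s, d_s = line.split(",")
            by_dim.setdefault(int(dim_s), []).append((float(b_s), float(d_s)))
    return [Barcode(dim=d, bars=np.array(by_dim[d]).reshape(-1, 2))
            for d in sorted(by_dim)]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_curve(curve, path: str | Path, meta: dict | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {
            "tau": curve.thresholds,
            "count": curve.counts,
            "percentage": curve.percentages,
        }
    )
    df.to_csv(path, index=False)
    _sidecar(path).write_text(json.dumps(meta or {}, indent=2, sort_keys=True))


def load_curve(path: str | Path):
    from .topo_features import PTCurve

    df = pd.read_csv(path)
    return PTCurve(
        thresholds=df["tau"].to_numpy(float),
        counts=df["count"].to_numpy(float),
        percentages=df["percentage"].to_numpy(float),
    )


def save_image(image, path: str | Path) -> None:
    path = Path(path)
    np.savetxt(path, image.pixels, delimiter=",")
    meta = {
        "grid_size": image.grid_size,
        "spread": image.spread,
        "domain": list(map(list, image.domain)),
        "weight": "linear_persistence",
        "pixel_rule": "gaussian_cdf_integral",
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def load_image(path: str | Path):
    from .topo_features import PersistenceImage

    path = Path(path)
    pixels = np.loadtxt(path, delimiter=",", ndmin=2)
    meta = json.loads(_sidecar(path).read_text())
    return PersistenceImage(
        grid_size=int(meta["grid_size"]),
        spread=float(meta["spread"]),
        domain=tuple(tuple(x) for x in meta["domain"]),
        pixels=pixels,
    )
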