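import numpy as np
import pytest

from flowtopo import fcs_io
from flowtopo.fcs_io import (
    CohortManifest,
    FCSFormatError,
    ManifestEntry,
    PointCloud,
    load_barcodes,
    load_curve,
    load_image,
    load_manifest,
    read_csv_cloud,
    read_fcs,
    save_barcodes,
    save_curve,
    save_image,
    save_manifest,
    write_csv_cloud,
    write_fcs_fixture,
)
from flowtopo.ph_core import Barcode
from flowtopo.topo_features import PTCurve, PersistenceImage


class TestPointCloud:
    def test_shape_validation(self):
        with pytest.raises(ValueError, match="marker count"):
            PointCloud("p", ["a"], np.zeros((3, 2)))

    def test_duplicate_markers_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            PointCloud("p", ["CD10", "CD10"], np.zeros((3, 2)))

    def test_column_lookup(self):
        c = PointCloud("p", ["a", "b"], np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert np.array_equal(c.column("b"), [2.0, 4.0])
        with pytest.raises(KeyError):
            c.column("z")


class TestFCSRoundTrip:
    def test_three_event_two_parameter(self, tmp_path):
        values = np.array([[1.5, 2.5], [3.0, -4.0], [0.0, 1e6]])
        cloud = PointCloud("p1", ["CD10", "CD20"], values)
        path = tmp_path / "p1.fcs"
        write_fcs_fixture(cloud, path)
        back = read_fcs(path)
        assert back.markers == ["CD10", "CD20"]
        assert back.values.shape == (3, 2)
        np.testing.assert_array_equal(back.values, values.astype(np.float32))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_clouds(self, tmp_path, seed):
        rng = np.random.default_rng(seed)
        n, p = int(rng.integers(1, 50)), int(rng.integers(1, 8))
        cloud = PointCloud(
            "r", [f"M{i}" for i in range(p)], rng.normal(size=(n, p)) * 100
        )
        path = tmp_path / "r.fcs"
        write_fcs_fixture(cloud, path)
        back = read_fcs(path)
        np.testing.assert_array_equal(back.values, cloud.values.astype(np.float32))
        assert back.markers == cloud.markers

    def test_one_cell_one_marker(self, tmp_path):
        path = tmp_path / "tiny.fcs"
        write_fcs_fixture(PointCloud("t", ["CD19"], np.array([[0.5]])), path)
        back = read_fcs(path)
        assert back.values.shape == (1, 1)

    def test_zero_events(self, tmp_path):
        path = tmp_path / "empty.fcs"
        write_fcs_fixture(PointCloud("e", ["A", "B"], np.empty((0, 2))), path)
        back = read_fcs(path)
        assert back.values.shape == (0, 2)
        assert back.markers == ["A", "B"]

    def test_inf_cloud_rejected(self, tmp_path):
        cloud = PointCloud("bad", ["A"], np.array([[np.inf]]))
        with pytest.raises(ValueError, match="finite"):
            write_fcs_fixture(cloud, tmp_path / "x.fcs")

    def test_empty_marker_list_rejected(self, tmp_path):
        cloud = PointCloud("bad", [], np.empty((3, 0)))
        with pytest.raises(ValueError, match="marker"):
            write_fcs_fixture(cloud, tmp_path / "x.fcs")


def _patch_keyword(path, old: bytes, new: bytes):
    raw = path.read_bytes()
    assert old in raw and len(old) == len(new)
    path.write_bytes(raw.replace(old, new))


class TestFCSErrors:
    @pytest.fixture
    def fcs_file(self, tmp_path):
        path = tmp_path / "f.fcs"
        write_fcs_fixture(
            PointCloud("f", ["A", "B"], np.arange(6, dtype=float).reshape(3, 2)), path
        )
        return path

    def test_unsupported_datatype(self, fcs_file):
        _patch_keyword(fcs_file, b"$DATATYPE/F", b"$DATATYPE/A")
        with pytest.raises(FCSFormatError, match="unsupported datatype"):
            read_fcs(fcs_file)

    def test_non_list_mode(self, fcs_file):
        _patch_keyword(fcs_file, b"$MODE/L", b"$MODE/C")
        with pytest.raises(FCSFormatError, match="MODE"):
            read_fcs(fcs_file)

    def test_truncated_data_segment(self, fcs_file):
        raw = fcs_file.read_bytes()
        fcs_file.write_bytes(raw[:-8])
        with pytest.raises(FCSFormatError, match="length mismatch"):
            read_fcs(fcs_file)

    def test_wrong_version(self, tmp_path):
        path = tmp_path / "v2.fcs"
        path.write_bytes(b"FCS2.0" + b" " * 100)
        with pytest.raises(FCSFormatError, match="version"):
            read_fcs(path)


class TestCSVCloud:
    def test_basic(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("CD10,CD20\n1,2\n3,4\n5,6\n7,8\n")
        cloud = read_csv_cloud(path, "p")
        assert cloud.values.shape == (4, 2)
        assert cloud.markers == ["CD10", "CD20"]

    def test_nan_row_dropped_and_logged(self, tmp_path, caplog):
        path = tmp_path / "c.csv"
        path.write_text("A,B\n1,2\nnan,4\n5,6\n7,8\n")
        with caplog.at_level("WARNING"):
            cloud = read_csv_cloud(path, "p")
        assert cloud.values.shape == (3, 2)
        assert "1" in caplog.text

    def test_non_numeric_row_dropped(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("A,B\n1,2\nfoo,4\n5,6\n")
        assert read_csv_cloud(path, "p").values.shape == (2, 2)

    def test_duplicate_header(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("CD10,CD10\n1,2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_csv_cloud(path, "p")

    def test_empty_file(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("")
        with pytest.raises(Exception):
            read_csv_cloud(path, "p")

    def test_round_trip(self, tmp_path, rng):
        cloud = PointCloud("rt", ["X", "Y", "Z"], rng.normal(size=(20, 3)))
        path = tmp_path / "rt.csv"
        write_csv_cloud(cloud, path)
        back = read_csv_cloud(path, "rt")
        np.testing.assert_allclose(back.values, cloud.values)
        assert back.markers == cloud.markers


class TestManifest:
    def _write(self, tmp_path, rows):
        for pid in {r.split(",")[0] for r in rows}:
            (tmp_path / f"{pid}.csv").write_text("CD10\n1\n")
        path = tmp_path / "manifest.csv"
        path.write_text(
            "patient_id,label,risk_group,split,path\n"
            + "\n".join(f"{r},{r.split(',')[0]}.csv" for r in rows)
            + "\n"
        )
        return path

    def test_valid(self, tmp_path):
        path = self._write(
            tmp_path, ["p1,R,low,discovery", "p2,NR,high,validation"]
        )
        m = load_manifest(path)
        assert len(m) == 2
        assert m.labels == ["R", "NR"]

    def test_unknown_label(self, tmp_path):
        path = self._write(tmp_path, ["p1,relapse,low,discovery"])
        with pytest.raises(ValueError, match=r"allowed.*R"):
            load_manifest(path)

    def test_duplicate_patient(self, tmp_path):
        path = self._write(
            tmp_path, ["p1,R,low,discovery", "p1,NR,low,discovery"]
        )
        with pytest.raises(ValueError, match="duplicate"):
            load_manifest(path)

    def test_missing_path(self, tmp_path):
        path = self._write(tmp_path, ["p1,R,low,discovery"])
        (tmp_path / "p1.csv").unlink()
        with pytest.raises(FileNotFoundError):
            load_manifest(path)

    def test_save_load_round_trip(self, tmp_path):
        (tmp_path / "a.csv").write_text("M\n1\n")
        m = CohortManifest(
            [ManifestEntry("a", "R", "intermediate", "validation", tmp_path / "a.csv")]
        )
        save_manifest(m, tmp_path / "m.csv")
        back = load_manifest(tmp_path / "m.csv")
        assert back.entries[0].patient_id == "a"
        assert back.entries[0].risk_group == "intermediate"

    def test_subset(self, tmp_path):
        path = self._write(
            tmp_path,
            ["p1,R,low,discovery", "p2,NR,low,discovery", "p3,NR,low,validation"],
        )
        m = load_manifest(path)
        assert len(m.subset(split="discovery")) == 2
        assert len(m.subset(label="NR", split="validation")) == 1


class TestArtifacts:
    def test_barcode_round_trip_exact(self, tmp_path, rng):
        bars0 = np.array([[0.0, 0.123456789012345], [0.0, np.inf]])
        bars1 = rng.uniform(0, 1, (5, 2))
        bars1 = np.column_stack([bars1.min(axis=1), bars1.max(axis=1) + 1e-3])
        bcs = [Barcode(0, bars0), Barcode(1, bars1)]
        path = tmp_path / "b.csv"
        save_barcodes(bcs, path)
        back = load_barcodes(path)
        assert back[0].dim == 0 and back[1].dim == 1
        np.testing.assert_array_equal(back[0].bars, bars0)
        np.testing.assert_array_equal(back[1].bars, bars1)

    def test_curve_round_trip(self, tmp_path):
        curve = PTCurve(
            thresholds=np.linspace(0.04, 0.05, 20),
            counts=np.arange(20, 0, -1.0),
            percentages=np.linspace(1, 0.1, 20),
        )
        path = tmp_path / "c.csv"
        save_curve(curve, path, meta={"dim": 1})
        back = load_curve(path)
        np.testing.assert_allclose(back.thresholds, curve.thresholds)
        np.testing.assert_allclose(back.counts, curve.counts)

    def test_image_round_trip(self, tmp_path, rng):
        img = PersistenceImage(5, 0.05, ((0.0, 1.0), (0.0, 1.0)), rng.uniform(size=(5, 5)))
        path = tmp_path / "i.csv"
        save_image(img, path)
        back = load_image(path)
        np.testing.assert_allclose(back.pixels, img.pixels)
        assert back.grid_size == 5 and back.spread == 0.05
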