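import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from flowtopo.fcs_io import PointCloud


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cloud(values, markers=None, patient_id="test"):
    values = np.asarray(values, float)
    if values.ndim == 1:
        values = values[:, None]
    if markers is None:
        markers = [f"M{i}" for i in range(values.shape[1])]
    return PointCloud(patient_id, list(markers), values)


@pytest.fixture
def cloud_factory():
    return make_cloud


def random_barcode(rng, n_bars, dim=1, scale=1.0):
    from flowtopo.ph_core import Barcode

    births = rng.uniform(0, 0.5 * scale, n_bars)
    deaths = births + rng.uniform(1e-6, 0.5 * scale, n_bars)
    return Barcode(dim=dim, bars=np.column_stack([births, deaths]))


@pytest.fixture
def barcode_factory():
    return random_barcode
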