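import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from grazescape.buffers import BufferProfile
from grazescape.landcover import ConfusionMatrix
from grazescape.raster import LandCoverRaster
from grazescape.scheme import DEFAULT_SCHEME

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


# --- published accuracy-assessment table (printed counts; row = classified,
# --- column = reference; class order CDW, ODW, CG, DG, AG, BU, CCW, BA, W)
TABLE2_ORDER = ("CDW", "ODW", "CG", "DG", "AG", "BU", "CCW", "BA", "W")
TABLE2_COUNTS = np.array(
    [
        [49, 3, 0, 2, 3, 0, 0, 0, 0],
        [0, 45, 0, 5, 2, 0, 2, 0, 0],
        [0, 0, 48, 5, 0, 2, 0, 0, 0],
        [0, 2, 2, 38, 0, 7, 0, 0, 0],
        [1, 0, 0, 0, 25, 0, 0, 0, 0],
        [0, 0, 0, 0, 0, 40, 0, 1, 0],
        [0, 0, 0, 0, 0, 0, 28, 0, 0],
        [0, 0, 0, 0, 0, 0, 0, 49, 0],
        [0, 0, 0, 0, 0, 1, 0, 0, 50],
    ]
)
TABLE2_USERS = dict(zip(TABLE2_ORDER, (85.96, 83.33, 87.27, 77.55, 96.15, 97.56, 100.00, 100.00, 98.04)))
TABLE2_PRODUCERS = dict(zip(TABLE2_ORDER, (98.00, 90.00, 96.00, 76.00, 83.33, 80.00, 93.33, 98.00, 100.00)))
TABLE2_OVERALL = 90.73


@pytest.fixture
def scheme():
    return DEFAULT_SCHEME


@pytest.fixture
def table2_matrix():
    codes = tuple(DEFAULT_SCHEME.code_of(a) for a in TABLE2_ORDER)
    return ConfusionMatrix(TABLE2_COUNTS.copy(), codes)


def make_raster(data, cell_size=30.0, origin=None, nodata=-9999):
    data = np.asarray(data, dtype=np.int32)
    if origin is None:
        origin = (0.0, data.shape[0] * cell_size)
    return LandCoverRaster(
        data=data, cell_size=cell_size, origin=origin, nodata=nodata
    )


@pytest.fixture
def uniform_raster():
    def _make(code, shape=(50, 50), cell_size=30.0):
        return make_raster(np.full(shape, code), cell_size=cell_size)

    return _make


@pytest.fixture
def checkerboard_raster():
    def _make(code_a, code_b, shape=(150, 150), cell_size=30.0):
        idx = np.add.outer(np.arange(shape[0]), np.arange(shape[1]))
        return make_raster(np.where(idx % 2 == 0, code_a, code_b), cell_size=cell_size)

    return _make


def brute_force_profile(raster, x, y, radius, sample_id=None):
    """Independent oracle: exhaustive loop over a padded lattice testing the
    pixel-centre distance rule, including off-grid member pixels."""
    rows, cols = raster.shape
    pad = int(math.ceil(radius / raster.cell_size)) + 2
    members = 0
    valid_values = []
    for i in range(-pad, rows + pad):
        for j in range(-pad, cols + pad):
            cx, cy = raster.cell_center(i, j)
            if (cx - x) ** 2 + (cy - y) ** 2 <= radius**2:
                members += 1
                if 0 <= i < rows and 0 <= j < cols and raster.data[i, j] != raster.nodata:
                    valid_values.append(int(raster.data[i, j]))
    n_valid = len(valid_values)
    props = {}
    for v in valid_values:
        props[v] = props.get(v, 0) + 1
    props = {k: 100.0 * c / n_valid for k, c in props.items()}
    return BufferProfile(
        sample_id=sample_id,
        radius_m=radius,
        proportions=props,
        valid_fraction=n_valid / members if members else 0.0,
        n_members=members,
        n_valid=n_valid,
    )


def make_profile(proportions, sample_id="s", radius=4000.0, valid_fraction=1.0):
    n_valid = 100 if valid_fraction > 0 else 0
    return BufferProfile(
        sample_id=sample_id,
        radius_m=radius,
        proportions=dict(proportions),
        valid_fraction=valid_fraction,
        n_members=100,
        n_valid=n_valid,
    )


def make_analysis_frame(rows):
    """rows: (locality, interval, season, grassiness, pct_c4) tuples."""
    return pd.DataFrame(
        rows, columns=["locality_id", "interval", "season", "grassiness", "pct_c4"]
    )
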