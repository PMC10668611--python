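import numpy as np
import pytest

from choroidtrace.core import BoundaryTrace, Segmentation


def make_segmentation(
    rpe_rows,
    cs_rows,
    lateral_scale=1.0,
    axial_scale=1.0,
    fovea_column=None,
    columns=None,
):
    """Build a Segmentation directly from row arrays (test helper)."""
    rpe_rows = np.asarray(rpe_rows, dtype=float)
    cs_rows = np.asarray(cs_rows, dtype=float)
    if columns is None:
        columns = np.arange(len(rpe_rows))
    if fovea_column is None:
        fovea_column = int(columns[len(columns) // 2])
    zeros = np.zeros(len(columns))
    return Segmentation(
        rpe_c=BoundaryTrace(columns, rpe_rows, zeros.copy()),
        c_s=BoundaryTrace(columns, cs_rows, zeros.copy()),
        scales=(lateral_scale, axial_scale),
        fovea_column=fovea_column,
    )


@pytest.fixture
def flat_segmentation():
    """Flat boundaries 100 px apart, unit scales, 801 columns."""
    n = 801
    return make_segmentation(
        np.full(n, 100.0), np.full(n, 200.0), fovea_column=400
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
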