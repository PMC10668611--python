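"""Fovea-referenced choroidal thickness and area in physical units.

All geometry is carried out in micron space (``x = column * lateral_scale``,
``y = row * axial_scale``) so that tangents, normals, and angles are
anatomical rather than pixel-grid artifacts: B-scans have very different
axial and lateral resolutions, and pixel-space angles would be misleading.
"""

from __future__ import annotations

import math

import numpy as np

from ._geometry import (
    ray_polyline_distance,
    signed_angle_deg,
    tangent_and_inward_normal,
)
from .core import (
    CaliperLine,
    CAMeasure,
    CTMeasure,
    InvalidParameterError,
    OutOfSpanError,
    Segmentation,
)

DEFAULT_OFFSETS_UM = (-2000.0, 0.0, 2000.0)
ETDRS_HALF_WIDTH_UM = 3000.0
TANGENT_HALF_WINDOW_UM = 50.0


def _trace_um(trace, scales):
    lat, ax = scales
    return trace.columns * lat, trace.rows * ax


def _snap_column(fovea_column: int, offset_um: float, lateral_scale: float) -> int:
    """Nearest-integer column for a fovea-relative offset, ties toward the fovea."""
    delta = offset_um / lateral_scale
    mag = abs(delta)
    frac = mag - math.floor(mag)
    snapped = math.floor(mag) if abs(frac - 0.5) < 1e-12 else round(mag)
    return fovea_column + int(math.copysign(snapped, delta)) if delta != 0 else fovea_column


def reference_columns(
    seg: Segmentation,
    offsets_um=DEFAULT_OFFSETS_UM,
    eye: str = "right",
) -> list[tuple[str, int]]:
    """Labeled measurement columns at fovea-relative lateral offsets.

    For a right eye (the default) negative offsets are temporal and positive
    nasal; a left eye swaps the labels.
    """
    lat = seg.scales[0]
    lo, hi = seg.common_span()
    out = []
    for off in offsets_um:
        col = _snap_column(seg.fovea_column, off, lat)
        if not lo <= col <= hi:
            raise OutOfSpanError(f"offset {off} um maps to column {col}, outside span")
        if off == 0:
            label = "subfoveal"
        elif (off > 0) == (eye == "right"):
            label = "nasal"
        else:
            label = "temporal"
        out.append((label, col))
    return out


def _local_normal(seg: Segmentation, column: int, tangent_window: int | None):
    """Unit inward normal of the RPE-C trace at a column, in micron space."""
    lat, _ = seg.scales
    if tangent_window is None:
        tangent_window = max(3, round(TANGENT_HALF_WINDOW_UM / lat))
    xs, ys = _trace_um(seg.rpe_c, seg.scales)
    x0 = column * lat
    _, normal = tangent_and_inward_normal(xs, ys, x0, tangent_window * lat)
    return normal


def perpendicular_ct(
    seg: Segmentation, column: int, tangent_window: int | None = None
) -> CTMeasure:
    """Thickness along the local inward perpendicular of the RPE-C junction.

    The tangent is a least-squares line over ``+-tangent_window`` columns
    (default: 50 um converted to columns); the thickness is the micron
    distance from the RPE-C point along the inward normal to the
    piecewise-linear C-S curve.
    """
    lo, hi = seg.common_span()
    if not lo <= column <= hi:
        raise OutOfSpanError(f"column {column} outside common span [{lo}, {hi}]")
    lat, ax = seg.scales
    anchor = np.array([column * lat, seg.rpe_c.row_at(column) * ax])
    normal = _local_normal(seg, column, tangent_window)
    xs_cs, ys_cs = _trace_um(seg.c_s, seg.scales)
    dist = ray_polyline_distance(anchor, normal, xs_cs, ys_cs)
    return CTMeasure(
        location_label="", mode="perpendicular", thickness=dist,
        angle_from_perpendicular=0.0, column=int(column),
    )


def parallel_ct(
    seg: Segmentation, caliper: CaliperLine, tangent_window: int | None = None
) -> CTMeasure:
    """Thickness along a caliper's own direction (mimicking the manual axis)."""
    lat, ax = seg.scales
    column = int(round(caliper.anchor[0] / lat))
    lo, hi = seg.common_span()
    if not lo <= column <= hi:
        raise OutOfSpanError(f"caliper anchor column {column} outside span")
    anchor = np.array(caliper.anchor, dtype=float)
    direction = np.array(caliper.direction, dtype=float)
    norm = np.hypot(*direction)
    if norm == 0:
        raise InvalidParameterError("caliper direction has zero length")
    direction = direction / norm
    xs_cs, ys_cs = _trace_um(seg.c_s, seg.scales)
    dist = ray_polyline_distance(anchor, direction, xs_cs, ys_cs)
    angle = measurement_angle(caliper, seg, tangent_window)
    return CTMeasure(
        location_label=caliper.location_label, mode="parallel", thickness=dist,
        angle_from_perpendicular=angle, column=column,
    )


def measurement_angle(
    caliper: CaliperLine, seg: Segmentation, tangent_window: int | None = None
) -> float:
    """Signed angle (degrees) between a caliper and the local perpendicular.

    Positive when the caliper is rotated from the inward normal toward the
    nasal side. Computed in micron space.
    """
    lat, _ = seg.scales
    column = int(round(caliper.anchor[0] / lat))
    normal = _local_normal(seg, column, tangent_window)
    return signed_angle_deg(caliper.direction, normal)


def choroid_area(
    seg: Segmentation, half_width_um: float = ETDRS_HALF_WIDTH_UM
) -> CAMeasure:
    """Integrated vertical boundary separation over the fovea-centered window.

    Trapezoidal integral of the (C-S minus RPE-C) vertical separation in
    microns over lateral microns across columns with
    ``|x - fovea_x| <= half_width_um``; returned in mm^2.
    """
    lat, ax = seg.scales
    lo, hi = seg.common_span()
    fovea_x = seg.fovea_column * lat
    x_lo, x_hi = fovea_x - half_width_um, fovea_x + half_width_um
    if x_lo < lo * lat - 1e-9 or x_hi > hi * lat + 1e-9:
        raise OutOfSpanError("measurement window extends beyond the trace span")
    cols = np.arange(lo, hi + 1)
    xs = cols * lat
    sep = (np.interp(cols, seg.c_s.columns, seg.c_s.rows)
           - np.interp(cols, seg.rpe_c.columns, seg.rpe_c.rows)) * ax
    # clip the window exactly at its micron bounds by adding interpolated ends
    inside = (xs >= x_lo) & (xs <= x_hi)
    x_win = np.concatenate([[x_lo], xs[inside], [x_hi]])
    s_win = np.concatenate(
        [[np.interp(x_lo, xs, sep)], sep[inside], [np.interp(x_hi, xs, sep)]]
    )
    x_win, idx = np.unique(x_win, return_index=True)
    s_win = s_win[idx]
    area_um2 = np.trapezoid(s_win, x_win)
    return CAMeasure(
        area=float(area_um2 / 1e6), half_width=float(half_width_um),
        fovea_column=seg.fovea_column,
    )


def average_ct(measures: list[CTMeasure]) -> float:
    """Mean thickness across macular locations: one value per scan."""
    if not measures:
        raise InvalidParameterError("average_ct requires at least one measure")
    return float(np.mean([m.thickness for m in measures]))
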