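"""Shared data structures for the choroid analysis pipeline.

Coordinate conventions
----------------------
Pixel indices are 0-based. Row 0 is the top of the image and rows increase
with depth (axial direction). Columns increase temporal-to-nasal for a
right eye. Physical coordinates are obtained as ``x = column *
lateral_scale`` and ``y = row * axial_scale``, both in microns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


class InvalidParameterError(ValueError):
    """A parameter violates its documented precondition."""


class OutOfSpanError(ValueError):
    """A requested location falls outside the traced column span."""


class MetadataError(ValueError):
    """Required acquisition metadata is missing or malformed."""


class NonIntersectingRayError(RuntimeError):
    """A measurement ray left the trace span before hitting the far boundary."""


class LowEvidenceError(RuntimeError):
    """Too few columns produced edge candidates for a reliable trace."""


class CrossingBoundariesError(RuntimeError):
    """The two traced boundaries cross: non-positive choroid thickness."""


class NumericalConditioningError(RuntimeError):
    """A covariance matrix was numerically singular."""


class DegenerateTestError(RuntimeError):
    """A statistical test is undefined on the supplied data."""


class DegenerateBandwidthWarning(UserWarning):
    """All KDE input values were identical; a point-mass fallback is used."""


@dataclass
class BScan:
    """A single cross-sectional OCT image with its physical calibration.

    ``pixels`` holds float intensities in [0, 1]; ``lateral_scale`` and
    ``axial_scale`` are microns per pixel; ``fovea_column`` is the column
    index of the foveal pit. ``meta`` carries acquisition metadata
    (decimal-hour daytime, scan focus, patient/visit identifiers).
    """

    pixels: np.ndarray
    lateral_scale: float
    axial_scale: float
    fovea_column: int
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise InvalidParameterError("pixels must be a 2-D grayscale array")
        if not np.all(np.isfinite(self.pixels)):
            raise InvalidParameterError("pixel intensities must be finite")
        if self.lateral_scale <= 0 or self.axial_scale <= 0:
            raise InvalidParameterError("pixel scales must be positive")
        if not 0 <= self.fovea_column < self.pixels.shape[1]:
            raise InvalidParameterError("fovea_column outside image width")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def replace_pixels(self, pixels: np.ndarray) -> "BScan":
        """Return a copy with new pixel data and untouched metadata."""
        return BScan(
            pixels=pixels,
            lateral_scale=self.lateral_scale,
            axial_scale=self.axial_scale,
            fovea_column=self.fovea_column,
            meta=dict(self.meta),
        )


@dataclass
class EdgeMap:
    """Nonnegative edge-strength image responding to one intensity polarity.

    ``polarity`` is ``"dark_to_bright"`` or ``"bright_to_dark"``, naming the
    axial (top-to-bottom) intensity transition the map responds to.
    """

    gradient: np.ndarray
    polarity: str

    def __post_init__(self) -> None:
        self.gradient = np.asarray(self.gradient, dtype=float)
        if self.gradient.ndim != 2:
            raise InvalidParameterError("gradient must be 2-D")
        if np.any(self.gradient < 0):
            raise InvalidParameterError("edge strengths must be nonnegative")
        if self.polarity not in ("dark_to_bright", "bright_to_dark"):
            raise InvalidParameterError(f"unknown polarity {self.polarity!r}")


@dataclass
class BoundaryTrace:
    """Sub-pixel boundary position per column with per-column uncertainty.

    ``columns`` is a contiguous, strictly increasing integer span; ``rows``
    the posterior mean row position per column; ``sd`` the posterior
    standard deviation in pixels. ``accepted_observations`` records the
    (column, row) edge pixels used as data.
    """

    columns: np.ndarray
    rows: np.ndarray
    sd: np.ndarray
    accepted_observations: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=int)
        self.rows = np.asarray(self.rows, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (len(self.columns) == len(self.rows) == len(self.sd)):
            raise InvalidParameterError("columns, rows, sd must share length")
        if len(self.columns) > 1 and np.any(np.diff(self.columns) <= 0):
            raise InvalidParameterError("columns must be strictly increasing")
        if np.any(self.sd < 0):
            raise InvalidParameterError("sd must be nonnegative")

    def row_at(self, column: float) -> float:
        """Linearly interpolated row position at a (possibly fractional) column."""
        return float(np.interp(column, self.columns, self.rows))


@dataclass
class GroundTruth:
    """True junction curves of a synthetic scan, on every generated column."""

    rpe_c: BoundaryTrace
    c_s: BoundaryTrace
    fovea_column: int
    scales: tuple[float, float]  # (lateral, axial) microns/pixel


@dataclass
class Segmentation:
    """A pair of boundary traces with the calibration needed to measure them."""

    rpe_c: BoundaryTrace
    c_s: BoundaryTrace
    scales: tuple[float, float]  # (lateral, axial) microns/pixel
    fovea_column: int

    def common_span(self) -> tuple[int, int]:
        lo = max(self.rpe_c.columns[0], self.c_s.columns[0])
        hi = min(self.rpe_c.columns[-1], self.c_s.columns[-1])
        if lo > hi:
            raise InvalidParameterError("traces share no common column span")
        return int(lo), int(hi)


@dataclass
class CaliperLine:
    """A straight-line thickness measurement in physical (micron) space."""

    anchor: tuple[float, float]  # (x, y) microns, on the RPE-C boundary
    direction: tuple[float, float]  # unit vector, points toward the C-S boundary
    length: float  # microns
    location_label: str  # temporal | subfoveal | nasal
    angle_deg: float = 0.0  # signed rotation from the local perpendicular
    valid: bool = True


@dataclass
class CTMeasure:
    """Choroidal thickness at a named macular location."""

    location_label: str
    mode: str  # perpendicular | parallel
    thickness: float  # microns
    angle_from_perpendicular: float  # degrees; 0 when mode == perpendicular
    column: int


@dataclass
class CAMeasure:
    """Choroidal area over the fovea-centered measurement window."""

    area: float  # mm^2
    half_width: float  # microns
    fovea_column: int
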