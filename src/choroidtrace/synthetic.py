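"""Ground-truth-known synthetic EDI-OCT B-scans, graders, and cohorts.

Every downstream stage of the pipeline is testable against this module:
:func:`generate_bscan` builds a layered speckled B-scan with exactly known
junction curves, :func:`simulate_manual_calipers` emulates a human grader
whose measurement axis deviates from the local perpendicular by a normally
distributed angle, and :func:`generate_cohort` produces longitudinal visit
tables whose choroid-to-renal-marker coefficients are known by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._geometry import (
    ray_polyline_distance,
    rotate_toward_nasal,
    tangent_and_inward_normal,
)
from .core import (
    BoundaryTrace,
    BScan,
    CaliperLine,
    GroundTruth,
    InvalidParameterError,
    NonIntersectingRayError,
)

# Default physical calibration. The lateral scale follows from an 8.7 mm
# field of view over 768 columns; the axial scale is a nominal
# spectral-domain device value and is configurable (it is an assumption,
# not a measured quantity).
DEFAULT_LATERAL_SCALE = 8700.0 / 768.0  # ~11.33 um/px
DEFAULT_AXIAL_SCALE = 3.87  # um/px

RPE_BAND_PX = 4  # thickness of the bright RPE band above the RPE-C junction
SHADOW_ATTENUATION = 0.45
VESSEL_INTENSITY = 0.12

Curve = Callable[[np.ndarray], np.ndarray]


def flat_curve(row: float) -> Curve:
    """Horizontal junction at a fixed row."""
    return lambda x: np.full_like(np.asarray(x, dtype=float), float(row))


def tilted_curve(row0: float, slope: float) -> Curve:
    """Straight junction: row = row0 + slope * column."""
    return lambda x: row0 + slope * np.asarray(x, dtype=float)


def sinusoidal_curve(
    mean_row: float, amplitude: float, period_px: float, phase: float = 0.0
) -> Curve:
    """Sinusoidal junction around ``mean_row``."""
    return lambda x: mean_row + amplitude * np.sin(
        2.0 * np.pi * np.asarray(x, dtype=float) / period_px + phase
    )


@dataclass
class SynthScanParams:
    """Parameters of one synthetic B-scan; see module docstring."""

    height_px: int = 768
    width_px: int = 768
    lateral_scale: float = DEFAULT_LATERAL_SCALE
    axial_scale: float = DEFAULT_AXIAL_SCALE
    fovea_column: int = 384
    rpe_curve: Curve = field(default_factory=lambda: flat_curve(300.0))
    cs_curve: Curve = field(default_factory=lambda: flat_curve(380.0))
    layer_intensities: dict[str, float] = field(
        default_factory=lambda: {
            "retina": 0.45,
            "rpe": 0.85,
            "choroid": 0.30,
            "sclera": 0.55,
        }
    )
    vessel_count: int = 0
    speckle_strength: float = 0.0
    shadow_columns: list[tuple[int, int]] = field(default_factory=list)
    seed: int = 0


@dataclass
class GraderParams:
    """Angular-error model of a simulated manual grader.

    The measurement axis is the local perpendicular to the RPE-C junction
    rotated by a draw from normal(angle_mean, angle_sd) degrees; the lateral
    landmark is jittered by normal(0, landmark_jitter_sd) microns.
    """

    angle_mean: float = 0.5
    angle_sd: float = 2.5
    landmark_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.angle_sd < 0 or self.landmark_jitter_sd < 0:
            raise InvalidParameterError("grader SDs must be nonnegative")


@dataclass
class CohortParams:
    """Longitudinal cohort generator parameters.

    ``choroid_marker_slopes`` are the standardized effects of choroidal
    thickness on each renal marker; ``daytime_effect`` the standardized
    effect of relative daytime. ``recipient_1yr_change`` / ``donor_1yr_change``
    are fractional one-year thickness changes, interpolated linearly in time.
    """

    n_donors: int = 20
    n_recipients: int = 16
    visit_weeks: Sequence[float] = (0, 1, 4, 8, 18, 28, 52)
    mean_baseline_ct: float = 270.0
    patient_sd: float = 60.0
    recipient_1yr_change: float = 0.141
    donor_1yr_change: float = -0.049
    choroid_marker_slopes: dict[str, float] = field(
        default_factory=lambda: {"egfr": 1.0, "creatinine": -0.9, "urea": -0.7}
    )
    daytime_effect: float = -0.4
    noise_sd: float = 0.5
    seed: int = 0
    # Measurement-error model for the two CT pathways: the simulated manual
    # grader tilts by normal(angle_mean, angle_sd) degrees and mis-marks the
    # boundary by normal(0, manual_marking_sd) microns; the automated reading
    # carries only ``auto_ct_sd`` microns of residual noise.
    grader_angle_mean: float = 0.5
    grader_angle_sd: float = 2.5
    manual_marking_sd: float = 0.0
    auto_ct_sd: float = 0.0
    marker_patient_sd: float | None = None  # defaults to noise_sd

    def __post_init__(self) -> None:
        weeks = list(self.visit_weeks)
        if not weeks or weeks[0] != 0:
            raise InvalidParameterError("visit_weeks must start at 0 (baseline)")
        if any(w < 0 for w in weeks):
            raise InvalidParameterError("visit weeks must be nonnegative")
        for name in ("patient_sd", "noise_sd", "grader_angle_sd",
                     "manual_marking_sd", "auto_ct_sd"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be nonnegative")


def _curve_rows(curve: Curve, width: int) -> np.ndarray:
    cols = np.arange(width, dtype=float)
    rows = np.asarray(curve(cols), dtype=float)
    if rows.shape != (width,):
        raise InvalidParameterError("curve must return one row per column")
    return rows


def generate_bscan(params: SynthScanParams) -> tuple[BScan, GroundTruth]:
    """Render a layered, speckled B-scan and its exact ground truth.

    The image stacks retina / bright RPE band / choroid / sclera along the
    axial direction following the two junction curves, adds dark elliptical
    vessels inside the choroid band, multiplicative gamma speckle of the
    requested strength, and attenuates any shadow column spans.
    """
    h, w = params.height_px, params.width_px
    rpe = _curve_rows(params.rpe_curve, w)
    cs = _curve_rows(params.cs_curve, w)
    if np.any(cs <= rpe):
        raise InvalidParameterError("cs_curve must lie strictly below rpe_curve")
    if np.any(rpe < RPE_BAND_PX) or np.any(cs >= h):
        raise InvalidParameterError("junction curves leave the image bounds")

    li = params.layer_intensities
    rows = np.arange(h, dtype=float)[:, None]
    img = np.full((h, w), li["retina"], dtype=float)
    img[(rows >= rpe - RPE_BAND_PX) & (rows < rpe)] = li["rpe"]
    img[(rows >= rpe) & (rows < cs)] = li["choroid"]
    img[rows >= cs] = li["sclera"]

    rng = np.random.default_rng(params.seed)

    # dark elliptical vessels confined to the choroid band
    for _ in range(params.vessel_count):
        c = rng.uniform(0, w)
        a = rng.uniform(8, 20)  # lateral semi-axis, px
        b = rng.uniform(4, 10)  # axial semi-axis, px
        col_idx = int(np.clip(round(c), 0, w - 1))
        lo = rpe[col_idx] + b + 2
        hi = cs[col_idx] - b - 2
        if hi <= lo:
            continue
        r = rng.uniform(lo, hi)
        rr = np.arange(h)[:, None]
        cc = np.arange(w)[None, :]
        mask = ((cc - c) / a) ** 2 + ((rr - r) / b) ** 2 <= 1.0
        # keep vessels strictly inside the band so the junctions stay intact
        mask &= (rr >= rpe + 1) & (rr <= cs - 2)
        img[mask] = VESSEL_INTENSITY

    if params.speckle_strength > 0:
        shape = 1.0 / params.speckle_strength**2
        img = img * rng.gamma(shape, scale=1.0 / shape, size=img.shape)

    for start, width in params.shadow_columns:
        if width <= 0 or start < 0 or start + width > w:
            raise InvalidParameterError("shadow span outside image width")
        img[:, start : start + width] *= SHADOW_ATTENUATION

    img = np.clip(img, 0.0, 1.0)

    scan = BScan(
        pixels=img,
        lateral_scale=params.lateral_scale,
        axial_scale=params.axial_scale,
        fovea_column=params.fovea_column,
        meta={"seed": params.seed, "synthetic": True},
    )
    cols = np.arange(w)
    zeros = np.zeros(w)
    gt = GroundTruth(
        rpe_c=BoundaryTrace(cols, rpe, zeros.copy()),
        c_s=BoundaryTrace(cols, cs, zeros.copy()),
        fovea_column=params.fovea_column,
        scales=(params.lateral_scale, params.axial_scale),
    )
    return scan, gt


def simulate_manual_calipers(
    gt: GroundTruth,
    grader: GraderParams,
    offsets_um: Sequence[float],
    rng: np.random.Generator | None = None,
    tangent_half_window_um: float = 50.0,
) -> list[CaliperLine]:
    """Simulate manual caliper measurements at fovea-relative offsets.

    Each caliper is anchored on the RPE-C curve at the (jittered) lateral
    landmark and directed along the local perpendicular rotated by a draw
    from normal(angle_mean, angle_sd) degrees, terminating at the C-S curve.
    Calipers that fail to intersect the C-S curve are returned with
    ``valid=False`` and zero length.
    """
    if rng is None:
        rng = np.random.default_rng(grader.seed)
    lat, ax = gt.scales
    xs = gt.rpe_c.columns * lat
    ys_rpe = gt.rpe_c.rows * ax
    xs_cs = gt.c_s.columns * lat
    ys_cs = gt.c_s.rows * ax
    fovea_x = gt.fovea_column * lat

    out: list[CaliperLine] = []
    for off in offsets_um:
        x_mark = fovea_x + off
        if not xs[0] <= x_mark <= xs[-1]:
            raise InvalidParameterError(f"offset {off} um outside lateral span")
        if grader.landmark_jitter_sd > 0:
            x_mark += rng.normal(0.0, grader.landmark_jitter_sd)
            x_mark = float(np.clip(x_mark, xs[0], xs[-1]))
        y_mark = float(np.interp(x_mark, xs, ys_rpe))
        _, normal = tangent_and_inward_normal(xs, ys_rpe, x_mark, tangent_half_window_um)
        theta = float(rng.normal(grader.angle_mean, grader.angle_sd))
        direction = rotate_toward_nasal(normal, theta)
        label = "subfoveal" if off == 0 else ("nasal" if off > 0 else "temporal")
        try:
            length = ray_polyline_distance(
                np.array([x_mark, y_mark]), direction, xs_cs, ys_cs
            )
            out.append(
                CaliperLine(
                    anchor=(x_mark, y_mark),
                    direction=(float(direction[0]), float(direction[1])),
                    length=length,
                    location_label=label,
                    angle_deg=theta,
                    valid=True,
                )
            )
        except NonIntersectingRayError:
            out.append(
                CaliperLine(
                    anchor=(x_mark, y_mark),
                    direction=(float(direction[0]), float(direction[1])),
                    length=0.0,
                    location_label=label,
                    angle_deg=theta,
                    valid=False,
                )
            )
    return out


# natural-unit affine maps for the simulated renal markers: value = loc + scale*z
_MARKER_AFFINE = {
    "egfr": (65.0, 15.0),
    "creatinine": (110.0, 35.0),
    "urea": (7.0, 2.0),
}


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = np.std(v, ddof=1)
    if sd == 0:
        return np.zeros_like(v)
    return (v - np.mean(v)) / sd


def generate_cohort(params: CohortParams) -> tuple[pd.DataFrame, dict]:
    """Generate a longitudinal visit table with known marker coefficients.

    Returns ``(table, truth)``. The table has one row per patient-visit with
    columns: patient, cohort, visit_week, daytime, relative_daytime, age,
    sex, scan_focus, auto_ct, manual_ct, auto_ca, egfr, creatinine, urea.

    ``truth`` records the generating coefficients and, per marker, the
    fully standardized coefficients a model that z-scores both response and
    predictors on this same table should recover (``std_beta``).
    """
    rng = np.random.default_rng(params.seed)
    weeks = np.asarray(list(params.visit_weeks), dtype=float)
    marker_patient_sd = (
        params.noise_sd if params.marker_patient_sd is None else params.marker_patient_sd
    )

    rows = []
    for cohort, n, change, prefix in (
        ("donor", params.n_donors, params.donor_1yr_change, "D"),
        ("recipient", params.n_recipients, params.recipient_1yr_change, "R"),
    ):
        for i in range(n):
            pid = f"{prefix}{i + 1:02d}"
            age = float(rng.normal(50.0, 11.0))
            sex = "M" if rng.random() < 0.5 else "F"
            focus = float(rng.normal(0.0, 1.5))
            b_ct = float(rng.normal(0.0, params.patient_sd))
            baseline_ct = params.mean_baseline_ct + b_ct
            base_daytime = float(rng.normal(13.0, 1.5))
            b_marker = {
                m: float(rng.normal(0.0, marker_patient_sd))
                for m in params.choroid_marker_slopes
            }
            for w in weeks:
                frac = w / 52.0
                true_ct = baseline_ct * (1.0 + change * frac)
                rel_dt = 0.0 if w == 0 else float(rng.normal(0.0, 1.0))
                theta = rng.normal(params.grader_angle_mean, params.grader_angle_sd)
                manual_ct = true_ct / math.cos(math.radians(theta))
                if params.manual_marking_sd > 0:
                    manual_ct += float(rng.normal(0.0, params.manual_marking_sd))
                auto_ct = true_ct
                if params.auto_ct_sd > 0:
                    auto_ct += float(rng.normal(0.0, params.auto_ct_sd))
                rows.append(
                    {
                        "patient": pid,
                        "cohort": cohort,
                        "visit_week": w,
                        "daytime": base_daytime + rel_dt,
                        "relative_daytime": rel_dt,
                        "age": age,
                        "sex": sex,
                        "scan_focus": focus,
                        "true_ct": true_ct,
                        "auto_ct": auto_ct,
                        "manual_ct": manual_ct,
                        "auto_ca": 6.0 * true_ct / 1000.0,  # mm^2, 6 mm window
                        "_b_marker": b_marker,
                    }
                )

    table = pd.DataFrame(rows)
    z_ct = _zscore(table["true_ct"].to_numpy())
    z_dt = _zscore(table["relative_daytime"].to_numpy())

    truth: dict = {
        "choroid_marker_slopes": dict(params.choroid_marker_slopes),
        "daytime_effect": params.daytime_effect,
        "std_beta": {},
    }
    for marker, slope in params.choroid_marker_slopes.items():
        b = np.array([bm[marker] for bm in table["_b_marker"]])
        eps = rng.normal(0.0, params.noise_sd, size=len(table)) if params.noise_sd > 0 else 0.0
        z_marker = slope * z_ct + params.daytime_effect * z_dt + b + eps
        loc, scale = _MARKER_AFFINE.get(marker, (0.0, 1.0))
        table[marker] = loc + scale * z_marker
        sd_y = float(np.std(z_marker, ddof=1))
        truth["std_beta"][marker] = {
            "choroid": slope / sd_y if sd_y > 0 else 0.0,
            "relative_daytime": params.daytime_effect / sd_y if sd_y > 0 else 0.0,
        }
    table = table.drop(columns=["_b_marker"])
    return table, truth
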