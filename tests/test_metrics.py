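import math

import numpy as np
import pytest

from choroidtrace import metrics
from choroidtrace._geometry import rotate_toward_nasal
from choroidtrace.core import CaliperLine, InvalidParameterError, OutOfSpanError

from conftest import make_segmentation


class TestReferenceColumns:
    def test_zero_offset_is_subfoveal(self, flat_segmentation):
        (label, col), = metrics.reference_columns(flat_segmentation, [0.0])
        assert label == "subfoveal"
        assert col == flat_segmentation.fovea_column

    def test_nearest_integer_snapping(self):
        seg = make_segmentation(
            np.full(768, 100.0), np.full(768, 200.0),
            lateral_scale=11.328, fovea_column=384,
        )
        (_, col), = metrics.reference_columns(seg, [2000.0])
        assert col == 384 + 177  # 2000 / 11.328 = 176.56 -> 177

    def test_three_locations(self):
        seg = make_segmentation(
            np.full(768, 100.0), np.full(768, 200.0),
            lateral_scale=11.328, fovea_column=384,
        )
        out = metrics.reference_columns(seg, [-2000.0, 0.0, 2000.0])
        assert [lbl for lbl, _ in out] == ["temporal", "subfoveal", "nasal"]
        assert len(out) == 3

    def test_left_eye_swaps_labels(self, flat_segmentation):
        out = metrics.reference_columns(flat_segmentation, [-100.0, 100.0], eye="left")
        assert [lbl for lbl, _ in out] == ["nasal", "temporal"]

    def test_half_pixel_ties_snap_toward_fovea(self):
        seg = make_segmentation(
            np.full(101, 10.0), np.full(101, 20.0),
            lateral_scale=100.0, fovea_column=50,
        )
        (_, col_pos), = metrics.reference_columns(seg, [250.0])  # 2.5 px
        (_, col_neg), = metrics.reference_columns(seg, [-250.0])
        assert col_pos == 52
        assert col_neg == 48

    def test_out_of_span(self, flat_segmentation):
        with pytest.raises(OutOfSpanError):
            metrics.reference_columns(flat_segmentation, [1e6])


class TestPerpendicularCT:
    def test_flat_traces(self):
        seg = make_segmentation(
            np.full(201, 100.0), np.full(201, 200.0), axial_scale=3.87
        )
        ct = metrics.perpendicular_ct(seg, 100)
        assert ct.thickness == pytest.approx(100 * 3.87, abs=1e-9)
        assert ct.angle_from_perpendicular == 0.0
        assert ct.mode == "perpendicular"

    def test_rotated_strip_normal_separation(self):
        # both boundaries tilted 20 deg in micron space, normal separation 250 um
        x = np.arange(2001, dtype=float)
        slope = math.tan(math.radians(20.0))
        rpe = 500.0 + slope * x
        cs = rpe + 250.0 / math.cos(math.radians(20.0))
        seg = make_segmentation(rpe, cs, fovea_column=1000)
        ct = metrics.perpendicular_ct(seg, 1000)
        assert ct.thickness == pytest.approx(250.0, abs=1.0)

    def test_flat_rpe_tilted_cs_measures_vertical(self):
        x = np.arange(501, dtype=float)
        rpe = np.full(501, 100.0)
        cs = 200.0 + 0.1 * x
        seg = make_segmentation(rpe, cs, fovea_column=250)
        ct = metrics.perpendicular_ct(seg, 250)
        assert ct.thickness == pytest.approx(200.0 + 0.1 * 250 - 100.0, abs=1e-6)

    def test_out_of_span(self, flat_segmentation):
        with pytest.raises(OutOfSpanError):
            metrics.perpendicular_ct(flat_segmentation, 5000)


def _flat_300um_seg(n=2001):
    # unit scales: rows are microns directly
    return make_segmentation(
        np.full(n, 500.0), np.full(n, 800.0), fovea_column=n // 2
    )


def _caliper_at_angle(seg, column, theta_deg):
    anchor = (float(column), float(seg.rpe_c.row_at(column)))
    direction = rotate_toward_nasal(np.array([0.0, 1.0]), theta_deg)
    return CaliperLine(
        anchor=anchor, direction=(direction[0], direction[1]),
        length=0.0, location_label="subfoveal",
    )


class TestParallelCT:
    def test_along_normal_equals_perpendicular(self):
        seg = _flat_300um_seg()
        cal = _caliper_at_angle(seg, 1000, 0.0)
        par = metrics.parallel_ct(seg, cal)
        perp = metrics.perpendicular_ct(seg, 1000)
        assert par.thickness == pytest.approx(perp.thickness, abs=1e-9)
        assert par.angle_from_perpendicular == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("theta,expected", [(60.0, 600.0), (8.1, 300.0 / math.cos(math.radians(8.1)))])
    def test_secant_relation(self, theta, expected):
        seg = _flat_300um_seg()
        cal = _caliper_at_angle(seg, 1000, theta)
        par = metrics.parallel_ct(seg, cal)
        assert par.thickness == pytest.approx(expected, abs=1e-6)
        assert par.angle_from_perpendicular == pytest.approx(theta, abs=1e-6)

    def test_parallel_at_least_perpendicular_on_flat_choroid(self):
        seg = _flat_300um_seg()
        perp = metrics.perpendicular_ct(seg, 1000).thickness
        for theta in (-10, -5, -1, 1, 5, 10):
            par = metrics.parallel_ct(seg, _caliper_at_angle(seg, 1000, theta))
            assert par.thickness > perp
        par0 = metrics.parallel_ct(seg, _caliper_at_angle(seg, 1000, 0.0))
        assert par0.thickness == pytest.approx(perp, abs=1e-9)

    def test_quadratic_error_law(self):
        seg = _flat_300um_seg()
        perp = metrics.perpendicular_ct(seg, 1000).thickness
        thetas = np.linspace(-10, 10, 41)
        diffs = np.array([
            metrics.parallel_ct(seg, _caliper_at_angle(seg, 1000, t)).thickness - perp
            for t in thetas
        ])
        t2 = np.deg2rad(thetas) ** 2
        slope, intercept = np.polyfit(t2, diffs, 1)
        pred = slope * t2 + intercept
        ss_res = np.sum((diffs - pred) ** 2)
        ss_tot = np.sum((diffs - diffs.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.99
        # t * theta^2 / 2 leading term; the theta^4 correction shifts the
        # fitted slope by ~1% over +-10 degrees
        assert slope == pytest.approx(300.0 / 2.0, rel=0.02)


class TestMeasurementAngle:
    def test_zero_along_normal(self):
        seg = _flat_300um_seg()
        angle = metrics.measurement_angle(_caliper_at_angle(seg, 1000, 0.0), seg)
        assert angle == pytest.approx(0.0, abs=1e-9)

    def test_constructed_rotation_recovered(self):
        seg = _flat_300um_seg()
        angle = metrics.measurement_angle(_caliper_at_angle(seg, 1000, 5.0), seg)
        assert angle == pytest.approx(5.0, abs=1e-6)

    def test_sign_convention_positive_toward_nasal(self):
        seg = _flat_300um_seg()
        pos = metrics.measurement_angle(_caliper_at_angle(seg, 1000, 4.0), seg)
        neg = metrics.measurement_angle(_caliper_at_angle(seg, 1000, -4.0), seg)
        assert pos > 0 > neg

    def test_invariance_under_pixel_anisotropy(self):
        # identical physical geometry sampled at two pixel calibrations
        slope_um = 0.2  # physical slope of the RPE-C line
        x_um = np.linspace(0, 8000, 769)

        def build(lat, ax):
            cols = np.arange(769)
            rpe_rows = (100.0 + slope_um * cols * lat) / ax
            cs_rows = rpe_rows + 300.0 / ax
            return make_segmentation(
                rpe_rows, cs_rows, lateral_scale=lat, axial_scale=ax,
                fovea_column=384,
            )

        seg_a = build(11.33, 3.87)
        seg_b = build(1.0, 1.0)
        direction = rotate_toward_nasal(
            np.array([-slope_um, 1.0]) / np.hypot(slope_um, 1.0), 7.0
        )
        for seg in (seg_a, seg_b):
            x_anchor = 384 * seg.scales[0]
            y_anchor = seg.rpe_c.row_at(384) * seg.scales[1]
            cal = CaliperLine(
                anchor=(x_anchor, y_anchor), direction=(direction[0], direction[1]),
                length=0.0, location_label="subfoveal",
            )
            angle = metrics.measurement_angle(cal, seg)
            assert angle == pytest.approx(7.0, abs=1e-6)

    def test_zero_length_caliper_rejected(self):
        seg = _flat_300um_seg()
        cal = CaliperLine(
            anchor=(1000.0, 500.0), direction=(0.0, 0.0), length=0.0,
            location_label="subfoveal",
        )
        with pytest.raises(InvalidParameterError):
            metrics.measurement_angle(cal, seg)


class TestChoroidArea:
    def test_uniform_thickness(self):
        seg = make_segmentation(
            np.full(8001, 100.0), np.full(8001, 350.0), fovea_column=4000
        )  # unit scales: 250 um thick
        ca = metrics.choroid_area(seg, half_width_um=3000.0)
        assert ca.area == pytest.approx(1.5, rel=1e-3)

    def test_zero_separation(self):
        rows = np.full(8001, 100.0)
        seg = make_segmentation(rows, rows.copy(), fovea_column=4000)
        assert metrics.choroid_area(seg).area == pytest.approx(0.0, abs=1e-12)

    def test_linear_ramp(self):
        x = np.arange(8001, dtype=float)
        fovea = 4000
        sep = np.clip((x - (fovea - 3000)) * 400.0 / 6000.0, 0, None)
        seg = make_segmentation(
            np.full(8001, 100.0), 100.0 + sep, fovea_column=fovea
        )
        ca = metrics.choroid_area(seg, half_width_um=3000.0)
        assert ca.area == pytest.approx(1.2, rel=1e-3)
        # cross-check against a fine-grid numeric integral oracle
        xs = np.linspace(fovea - 3000, fovea + 3000, 600_001)
        oracle = np.trapezoid(np.interp(xs, x, sep), xs) / 1e6
        assert ca.area == pytest.approx(oracle, rel=1e-6)

    def test_window_shortfall(self):
        seg = make_segmentation(np.full(100, 10.0), np.full(100, 20.0))
        with pytest.raises(OutOfSpanError):
            metrics.choroid_area(seg, half_width_um=3000.0)


class TestAverageCT:
    def test_mean(self):
        measures = [
            metrics.CTMeasure("a", "perpendicular", t, 0.0, 0)
            for t in (240.0, 270.0, 300.0)
        ]
        assert metrics.average_ct(measures) == pytest.approx(270.0)

    def test_single(self):
        m = metrics.CTMeasure("a", "perpendicular", 123.0, 0.0, 0)
        assert metrics.average_ct([m]) == 123.0

    def test_permutation_invariant(self):
        ms = [metrics.CTMeasure("a", "perpendicular", t, 0.0, 0) for t in (1.0, 2.0, 4.0)]
        assert metrics.average_ct(ms) == metrics.average_ct(ms[::-1])

    def test_empty_rejected(self):
        with pytest.raises(InvalidParameterError):
            metrics.average_ct([])
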