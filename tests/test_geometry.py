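"""Per-gland morphology: PCA axis, chord sampling, width/length/distortion."""

import numpy as np
import pytest

import meibomorph as mb
from meibomorph.errors import DegenerateGeometryError
from meibomorph.geometry import SamplingStation, _valid

from conftest import rect_mask


def contour_of(mask):
    cs = mb.extract_contours(mask)
    assert len(cs) == 1
    return cs[0]


def station(t, lo, hi):
    lo, hi = np.asarray(lo, float), np.asarray(hi, float)
    mid = (lo + hi) / 2
    return SamplingStation(t, tuple(lo), tuple(hi), tuple(mid),
                           float(np.linalg.norm(hi - lo)), True)


def midpoint_stations(points):
    """Stations whose midpoints are the given polyline (chords degenerate)."""
    out = []
    for i, p in enumerate(points):
        p = np.asarray(p, float)
        out.append(SamplingStation(float(i), tuple(p - [0.5, 0]), tuple(p + [0.5, 0]),
                                   tuple(p), 1.0, True))
    return out


# ---------------------------------------------------------------- axis


def test_principal_axis_of_wide_rectangle_is_horizontal():
    c = contour_of(rect_mask((60, 140), 20, 30, 15, 115))  # 100 wide, 10 tall
    ax = mb.principal_axis(c)
    assert ax.direction[0] == pytest.approx(1.0, abs=1e-3)
    assert abs(ax.direction[1]) < 1e-3
    assert ax.elongation > 10


def test_principal_axis_rotated_rectangle():
    # 100x10 rectangle rotated 45 deg, built analytically then rasterized
    spec = mb.GlandSpec(anchor=(100, 100), orientation=np.pi / 4,
                        centerline_length=100, width=10)
    c = contour_of(mb.rasterize_gland(spec, (200, 200)))
    ax = mb.principal_axis(c)
    assert ax.direction[0] == pytest.approx(np.sqrt(0.5), abs=0.02)
    assert abs(ax.direction[1]) == pytest.approx(np.sqrt(0.5), abs=0.02)


def test_principal_axis_sign_normalized_and_degenerate():
    c = contour_of(rect_mask((40, 40), 5, 35, 15, 25))  # tall rectangle
    ax = mb.principal_axis(c)
    assert ax.direction[0] > 0 or (ax.direction[0] == 0 and ax.direction[1] > 0)
    assert np.hypot(*ax.direction) == pytest.approx(1.0, abs=1e-9)
    degenerate = mb.GlandContour(np.tile([[3.0, 3.0]], (5, 1)), 10, (3.0, 3.0))
    with pytest.raises(DegenerateGeometryError):
        mb.principal_axis(degenerate)


def test_principal_axis_circle_is_isotropic():
    ys, xs = np.mgrid[0:80, 0:80]
    circ = mb.SegmentationMask((xs - 40) ** 2 + (ys - 40) ** 2 <= 30**2)
    ax = mb.principal_axis(contour_of(circ))
    assert ax.elongation == pytest.approx(1.0, abs=0.05)


# ---------------------------------------------------------------- stations


def test_stations_on_rectangle_have_constant_chords():
    c = contour_of(rect_mask((60, 160), 25, 35, 20, 120))  # 100 x 10
    ax = mb.principal_axis(c)
    stations = mb.sample_stations(c, ax, 50)
    assert len(stations) == 50
    valid = _valid(stations)
    assert len(valid) >= 48
    for s in valid:
        # end chords may cross the bevelled sub-pixel corners of the
        # iso-contour polygon; everywhere else the chord is the exact width
        assert s.chord_len == pytest.approx(10, abs=1.1)
        assert np.allclose(s.midpoint,
                           (np.asarray(s.p_low) + np.asarray(s.p_high)) / 2)
    interior = valid[2:-2]
    for s in interior:
        assert s.chord_len == pytest.approx(10, abs=0.5)


def test_station_t_values_equidistant_inclusive():
    c = contour_of(rect_mask((60, 160), 25, 35, 20, 120))
    ax = mb.principal_axis(c)
    ts = [s.t for s in mb.sample_stations(c, ax, 10)]
    assert np.allclose(np.diff(ts), ts[1] - ts[0])


# ---------------------------------------------------------------- metrics


def test_width_mean_of_valid_chords():
    sts = [station(0, (0, 0), (0, 10)), station(1, (1, 0), (1, 20))]
    assert mb.gland_width(sts) == pytest.approx(15.0)
    with pytest.raises(DegenerateGeometryError):
        mb.gland_width([])


def test_length_collinear_midpoints():
    sts = midpoint_stations([(0, 0), (0, 3), (0, 7), (0, 20)])
    assert mb.gland_length(sts) == pytest.approx(20.0)
    with pytest.raises(DegenerateGeometryError):
        mb.gland_length(sts[:1])


def test_distortion_zero_for_collinear_midline():
    sts = midpoint_stations([(0, i) for i in range(10)])
    assert mb.gland_distortion(sts) == pytest.approx(0.0, abs=1e-12)


def test_distortion_of_circle_midline_recovers_radius():
    R = 100.0
    theta = np.linspace(0, np.pi / 2, 50)
    pts = np.column_stack([R * np.cos(theta), R * np.sin(theta)])
    d = mb.gland_distortion(midpoint_stations(pts))
    assert d == pytest.approx(1 / R, rel=0.15)


def test_distortion_halves_under_doubling():
    rng = np.random.default_rng(0)
    theta = np.linspace(0, 1.2, 40)
    pts = np.column_stack([80 * np.cos(theta), 80 * np.sin(theta)])
    d1 = mb.gland_distortion(midpoint_stations(pts))
    d2 = mb.gland_distortion(midpoint_stations(2 * pts))
    assert d2 == pytest.approx(d1 / 2, rel=1e-9)


# ------------------------------------------------------------- measure


def test_measure_straight_gland_recovers_truth():
    spec = mb.GlandSpec(anchor=(150, 150), orientation=np.pi / 2,
                        centerline_length=150, width=12)
    m = mb.rasterize_gland(spec, (300, 300))
    mo = mb.measure_gland(contour_of(m))
    # measured length spans tip to tip (centerline + round caps)
    assert mo.width_px == pytest.approx(12, rel=0.08)
    assert mo.length_px == pytest.approx(150, rel=0.08)
    assert mo.distortion < 1e-3
    assert mo.n_valid_stations <= 50


def test_measure_arc_gland_recovers_curvature():
    spec = mb.GlandSpec(anchor=(200, 120), orientation=np.pi / 2,
                        centerline_length=200, width=12,
                        curvature=0.01, shape="arc")
    mo = mb.measure_gland(contour_of(mb.rasterize_gland(spec, (400, 400))))
    assert mo.distortion == pytest.approx(0.01, rel=0.15)
    assert mo.length_px == pytest.approx(200, rel=0.10)


def test_measure_translation_invariant():
    spec = mb.GlandSpec(anchor=(80, 100), orientation=np.pi / 2 + 0.05,
                        centerline_length=120, width=10,
                        curvature=0.005, shape="arc")
    m = mb.rasterize_gland(spec, (220, 160))
    shifted = mb.SegmentationMask(np.roll(np.roll(m.grid, 17, axis=0), 23, axis=1))
    a = mb.measure_gland(contour_of(m))
    b = mb.measure_gland(contour_of(shifted))
    assert a.length_px == pytest.approx(b.length_px, abs=1e-9)
    assert a.width_px == pytest.approx(b.width_px, abs=1e-9)
    assert a.distortion == pytest.approx(b.distortion, abs=1e-9)


def test_measure_rotation_invariant_within_tolerance():
    results = []
    for theta in (np.pi / 2, np.pi / 2 + np.pi / 6):
        spec = mb.GlandSpec(anchor=(200, 200), orientation=theta,
                            centerline_length=150, width=12,
                            curvature=0.006, shape="arc")
        results.append(mb.measure_gland(contour_of(mb.rasterize_gland(spec, (400, 400)))))
    a, b = results
    assert b.length_px == pytest.approx(a.length_px, rel=0.07)
    assert b.width_px == pytest.approx(a.width_px, rel=0.07)


def test_measure_scale_covariance():
    s1 = mb.GlandSpec(anchor=(200, 200), orientation=np.pi / 2, shape="arc",
                      centerline_length=150, width=12, curvature=0.006)
    s2 = mb.GlandSpec(anchor=(400, 400), orientation=np.pi / 2, shape="arc",
                      centerline_length=300, width=24, curvature=0.003)
    m1 = mb.measure_gland(contour_of(mb.rasterize_gland(s1, (400, 400))))
    m2 = mb.measure_gland(contour_of(mb.rasterize_gland(s2, (800, 800))))
    assert m2.length_px == pytest.approx(2 * m1.length_px, rel=0.05)
    assert m2.width_px == pytest.approx(2 * m1.width_px, rel=0.05)
    assert m2.distortion == pytest.approx(m1.distortion / 2, rel=0.05)


def test_measured_length_monotone_in_true_length():
    lengths = [80, 120, 160, 220, 280]
    measured = []
    for L in lengths:
        spec = mb.GlandSpec(anchor=(320, 320), orientation=np.pi / 2,
                            centerline_length=L, width=10)
        measured.append(
            mb.measure_gland(contour_of(mb.rasterize_gland(spec, (640, 640)))).length_px
        )
    assert all(b > a for a, b in zip(measured, measured[1:]))


def test_measure_isotropic_blob_reports_nan():
    ys, xs = np.mgrid[0:60, 0:60]
    circ = mb.SegmentationMask((xs - 30) ** 2 + (ys - 30) ** 2 <= 20**2)
    with pytest.warns(UserWarning):
        mo = mb.measure_gland(contour_of(circ))
    assert np.isnan(mo.length_px) and np.isnan(mo.width_px) and np.isnan(mo.distortion)
    assert mo.area_px > 0
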