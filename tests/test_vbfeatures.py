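import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vbmorph.vbfeatures import (
    Baseline,
    MjVBFeatures,
    MnVBFeatures,
    OvalAnnotation,
    RectAnnotation,
    SceneAnnotation,
    assemble_feature_vector,
    baseline_from_rects,
    brute_force_tour_length,
    contour_geometry,
    eccentricity,
    fit_ellipse,
    mjvb_features,
    mnvb_features,
    mnvb_ratio,
    mnvb_ratio2,
    salesman_ratio,
    shortest_tour_length,
)

from .conftest import circle_contour, ellipse_contour


def rect(cx, cy, w=10.0, h=10.0):
    return RectAnnotation(centre=(cx, cy), width=w, height=h)


HBASE = Baseline((0.0, 0.0), (100.0, 0.0))


# ---------------------------------------------------------------------------
# baseline
# ---------------------------------------------------------------------------

def test_baseline_length_horizontal():
    assert baseline_from_rects(rect(0, 0), rect(100, 0)).length == pytest.approx(100.0)


def test_baseline_length_345():
    assert baseline_from_rects(rect(0, 0), rect(3, 4)).length == pytest.approx(5.0)


def test_baseline_coincident_centres_raise():
    with pytest.raises(ValueError, match="degenerate"):
        baseline_from_rects(rect(5, 5), rect(5, 5))


# ---------------------------------------------------------------------------
# ratio / ratio2
# ---------------------------------------------------------------------------

def test_ratio_sums_perpendicular_distances():
    assert mnvb_ratio([(10, 5), (90, -15)], HBASE) == pytest.approx(0.2)


def test_ratio_zero_on_baseline():
    assert mnvb_ratio([(10, 0), (50, 0)], HBASE) == 0.0


def test_ratio_mirror_symmetric():
    pts = [(20, 7), (60, -3), (80, 11)]
    mirrored = [(x, -y) for x, y in pts]
    assert mnvb_ratio(pts, HBASE) == pytest.approx(mnvb_ratio(mirrored, HBASE))


def test_ratio_empty_is_zero():
    assert mnvb_ratio([], HBASE) == 0.0


def test_ratio2_single_centre():
    assert mnvb_ratio2([(50, 10)], HBASE) == pytest.approx(0.1)


def test_ratio2_midpoint_is_zero():
    assert mnvb_ratio2([(50, 0)], HBASE) == 0.0


def test_ratio2_two_points():
    assert mnvb_ratio2([(30, 0), (70, 0)], HBASE) == pytest.approx(0.4)


# ---------------------------------------------------------------------------
# travelling-salesman statistic
# ---------------------------------------------------------------------------

def test_tour_unit_square():
    length, _ = shortest_tour_length([(0, 0), (1, 0), (1, 1), (0, 1)])
    assert length == pytest.approx(4.0)


def test_tour_triangle_is_perimeter():
    pts = [(0, 0), (4, 0), (0, 3)]
    length, _ = shortest_tour_length(pts)
    assert length == pytest.approx(3 + 4 + 5)


def test_tour_degenerate_sizes():
    assert shortest_tour_length([])[0] == 0.0
    assert shortest_tour_length([(3, 3)])[0] == 0.0
    assert shortest_tour_length([(0, 0), (0, 5)])[0] == pytest.approx(10.0)


def test_tour_eight_random_points_match_brute_force():
    pts = np.random.default_rng(42).random((8, 2)) * 100
    length, tour = shortest_tour_length(pts)
    assert length == pytest.approx(brute_force_tour_length(pts))
    assert sorted(tour) == list(range(8))


@given(st.integers(0, 2**32 - 1), st.integers(3, 9))
@settings(max_examples=40, deadline=None)
def test_tour_exact_matches_brute_force(seed, n):
    pts = np.random.default_rng(seed).random((n, 2)) * 50
    assert shortest_tour_length(pts)[0] == pytest.approx(brute_force_tour_length(pts))


def test_tour_heuristic_not_below_optimum():
    # run the heuristic branch on an instance small enough to solve exactly
    import time

    import vbmorph.vbfeatures as vf

    pts = np.random.default_rng(5).random((10, 2)) * 100
    exact = brute_force_tour_length(pts)
    dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    tour = vf._two_opt(dist, vf._nearest_neighbour(dist), time.monotonic() + 1.0)
    assert vf._tour_length(dist, tour) >= exact - 1e-9


def test_salesman_ratio_unit_square():
    b = Baseline((0.0, 0.0), (2.0, 0.0))
    assert salesman_ratio([(0, 0), (1, 0), (1, 1), (0, 1)], b) == pytest.approx(2.0)


def test_salesman_ratio_single_point_is_zero():
    assert salesman_ratio([(5, 5)], HBASE) == 0.0


def test_salesman_ratio_scale_invariant():
    pts = np.random.default_rng(1).random((6, 2)) * 40
    b = Baseline((0.0, 0.0), (80.0, 0.0))
    b2 = Baseline((0.0, 0.0), (160.0, 0.0))
    assert salesman_ratio(pts, b) == pytest.approx(salesman_ratio(pts * 2, b2))


# ---------------------------------------------------------------------------
# scene-level MnVB features
# ---------------------------------------------------------------------------

def scene_with(centres, label=None):
    return SceneAnnotation(
        mjvb_rects=(rect(0, 0), rect(100, 0)),
        mnvb_ovals=[OvalAnnotation(centre=c) for c in centres],
        label=label,
    )


def test_mnvb_features_empty_scene():
    mn = mnvb_features(scene_with([]))
    assert mn == MnVBFeatures(number=0, ratio=0.0, ratio2=0.0, salesman_ratio=0.0)


def test_mnvb_features_rigid_motion_invariant():
    centres = [(20.0, 4.0), (45.0, -6.0), (70.0, 2.0)]
    base = mnvb_features(scene_with(centres))

    angle, tx, ty = 0.83, 31.0, -12.0
    c, s = math.cos(angle), math.sin(angle)

    def tf(p):
        return (c * p[0] - s * p[1] + tx, s * p[0] + c * p[1] + ty)

    moved = SceneAnnotation(
        mjvb_rects=(rect(*tf((0, 0))), rect(*tf((100, 0)))),
        mnvb_ovals=[OvalAnnotation(centre=tf(p)) for p in centres],
    )
    got = mnvb_features(moved)
    assert got.number == base.number
    for name in ("ratio", "ratio2", "salesman_ratio"):
        assert abs(getattr(got, name) - getattr(base, name)) < 1e-9


@given(st.floats(0.5, 20.0))
@settings(max_examples=20, deadline=None)
def test_mnvb_features_uniform_scale_invariant(scale):
    centres = [(20.0, 4.0), (45.0, -6.0), (70.0, 2.0), (90.0, 9.0)]
    base = mnvb_features(scene_with(centres))
    scaled = SceneAnnotation(
        mjvb_rects=(rect(0, 0, 10 * scale, 10 * scale), rect(100 * scale, 0, 10 * scale, 10 * scale)),
        mnvb_ovals=[OvalAnnotation(centre=(x * scale, y * scale)) for x, y in centres],
    )
    got = mnvb_features(scaled)
    for name in ("ratio", "ratio2", "salesman_ratio"):
        assert abs(getattr(got, name) - getattr(base, name)) < 1e-9


def test_scene_requires_two_rects():
    with pytest.raises(ValueError, match="exactly two"):
        SceneAnnotation(mjvb_rects=(rect(0, 0),))


def test_scene_warns_on_centre_outside_baseline_span():
    with pytest.warns(UserWarning, match="projects outside"):
        scene_with([(150.0, 0.0)])


# ---------------------------------------------------------------------------
# contour geometry
# ---------------------------------------------------------------------------

UNIT_SQUARE = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)


def test_geometry_unit_square():
    g = contour_geometry(UNIT_SQUARE)
    assert (g.area, g.perimeter, g.length, g.width) == pytest.approx((1, 4, 1, 1))


def test_geometry_circle_closed_forms():
    g = contour_geometry(circle_contour(r=10, n=512))
    assert g.area == pytest.approx(100 * math.pi, rel=1e-3)
    assert g.perimeter == pytest.approx(20 * math.pi, rel=1e-3)


def test_geometry_rotated_rectangle_oriented_box():
    pts = np.array([[0, 0], [4, 0], [4, 2], [0, 2]], dtype=float)
    a = math.radians(30)
    R = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
    g = contour_geometry(pts @ R.T)
    assert g.length == pytest.approx(4.0)
    assert g.width == pytest.approx(2.0)


def test_geometry_rejects_degenerate():
    with pytest.raises(ValueError):
        contour_geometry(UNIT_SQUARE[:2])
    with pytest.raises(ValueError, match="zero area"):
        contour_geometry(np.array([[0, 0], [1, 1], [2, 2]], dtype=float))


# ---------------------------------------------------------------------------
# ellipse fit
# ---------------------------------------------------------------------------

def test_fit_ellipse_recovers_axes():
    fit = fit_ellipse(ellipse_contour(5, 3, angle=0.6, centre=(12, -7)))
    assert fit.major_a == pytest.approx(5.0, abs=1e-6)
    assert fit.minor_b == pytest.approx(3.0, abs=1e-6)
    assert fit.residual < 1e-6


def test_fit_ellipse_circle():
    fit = fit_ellipse(circle_contour(r=7, n=128))
    assert fit.major_a == pytest.approx(7.0, abs=1e-6)
    assert fit.minor_b == pytest.approx(7.0, abs=1e-6)
    assert fit.residual < 1e-6


def test_fit_ellipse_residual_tracks_noise():
    rng = np.random.default_rng(3)
    sigma = 0.4
    theta = np.linspace(0, 2 * np.pi, 512, endpoint=False)
    r = 50 + rng.normal(0, sigma, 512)
    pts = np.c_[r * np.cos(theta), r * np.sin(theta)]
    fit = fit_ellipse(pts)
    assert fit.residual == pytest.approx(sigma, rel=0.2)


def test_fit_ellipse_rejects_collinear():
    with pytest.raises(ValueError):
        fit_ellipse(np.c_[np.arange(10.0), 2 * np.arange(10.0)])


def test_fit_ellipse_rejects_few_points():
    with pytest.raises(ValueError, match="6 distinct"):
        fit_ellipse(np.array([[0, 0], [1, 0], [0, 1], [1, 1], [2, 0]], dtype=float))


# ---------------------------------------------------------------------------
# eccentricity
# ---------------------------------------------------------------------------

def test_eccentricity_values():
    assert eccentricity(5, 3) == pytest.approx(0.8)
    assert eccentricity(5, 5) == 0.0
    assert eccentricity(5, 0) == 1.0


def test_eccentricity_rejects_bad_axes():
    with pytest.raises(ValueError):
        eccentricity(3, 5)
    with pytest.raises(ValueError):
        eccentricity(0, 0)


@given(st.floats(0.01, 0.99), st.floats(0.001, 0.009))
@settings(max_examples=30)
def test_eccentricity_strictly_decreasing_in_axis_ratio(ratio, delta):
    assert eccentricity(1.0, ratio) > eccentricity(1.0, ratio + delta)


# ---------------------------------------------------------------------------
# MjVB shape features
# ---------------------------------------------------------------------------

def densify(poly, per_edge=12):
    """Insert points along each edge so the ellipse-fit stage has support."""
    out = []
    closed = np.vstack([poly, poly[:1]])
    for p, q in zip(closed[:-1], closed[1:]):
        t = np.linspace(0, 1, per_edge, endpoint=False)[:, None]
        out.append(p + t * (q - p))
    return np.vstack(out)


def test_mjvb_square_features():
    s = 6.0
    f = mjvb_features(densify(UNIT_SQUARE * s))
    assert f.form_factor == pytest.approx(math.pi / 4)
    assert f.aspect_ratio == pytest.approx(1.0)
    assert f.rectangularity == pytest.approx(s / 4)


def test_mjvb_circle_features():
    f = mjvb_features(circle_contour(r=30, n=512))
    assert f.form_factor >= 0.999
    assert f.form_factor <= 1 + 1e-3
    assert f.eccentricity < 0.01


def test_mjvb_rectangle_features():
    pts = densify(np.array([[0, 0], [4, 0], [4, 2], [0, 2]], dtype=float))
    f = mjvb_features(pts)
    assert f.aspect_ratio == pytest.approx(2.0)
    assert f.rectangularity == pytest.approx(8 / 12)


@given(st.integers(0, 2**32 - 1))
@settings(max_examples=25, deadline=None)
def test_form_factor_respects_isoperimetric_bound(seed):
    rng = np.random.default_rng(seed)
    # star-convex random polygon
    theta = np.sort(rng.uniform(0, 2 * np.pi, 40))
    r = rng.uniform(5, 20, 40)
    pts = np.c_[r * np.cos(theta), r * np.sin(theta)]
    g = contour_geometry(pts)
    assert 4 * math.pi * g.area / g.perimeter**2 <= 1 + 1e-3


# ---------------------------------------------------------------------------
# feature vector assembly
# ---------------------------------------------------------------------------

MN = MnVBFeatures(number=3, ratio=0.1, ratio2=0.2, salesman_ratio=1.5)


def mk_mj(ff):
    return MjVBFeatures(form_factor=ff, aspect_ratio=1.2, rectangularity=5.0,
                        eccentricity=0.5, residual=0.3)


def test_assemble_pair_identical_members():
    fv = assemble_feature_vector(MN, [mk_mj(0.7), mk_mj(0.7)])
    assert fv.form_factor == pytest.approx(0.7)


def test_assemble_single_passthrough():
    fv = assemble_feature_vector(MN, [mk_mj(0.63)], label="x")
    assert fv.form_factor == pytest.approx(0.63)
    assert fv.label == "x"
    assert fv.number == 3.0


def test_assemble_pair_mean():
    fv = assemble_feature_vector(MN, [mk_mj(0.6), mk_mj(0.8)])
    assert fv.form_factor == pytest.approx(0.7)


def test_assemble_first_only_mode():
    fv = assemble_feature_vector(MN, [mk_mj(0.6), mk_mj(0.8)], combine="first")
    assert fv.form_factor == pytest.approx(0.6)


def test_assemble_empty_raises():
    with pytest.raises(ValueError, match="at least one"):
        assemble_feature_vector(MN, [])


def test_feature_vector_canonical_order():
    fv = assemble_feature_vector(MN, [mk_mj(0.6)])
    arr = fv.as_array()
    assert arr.shape == (9,)
    assert arr[0] == 3.0 and arr[4] == pytest.approx(0.6)
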