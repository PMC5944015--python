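"""Leaf-curve fitting and the six component phenotypes, against closed forms.

The independent oracles here are analytic: arc length of y = x^2 on [0, 1]
is sqrt(5)/2 + asinh(2)/4; curvature of x^2 at the origin is exactly 2; the
area between x(1-x) and its chord on [0, 1] is 1/6.
"""

import math

import numpy as np
import pytest

from phenoshoot import component_phenotypes as comp
from phenoshoot import segmentation as seg
from phenoshoot import skeleton_graph as sg
from phenoshoot import synthetic_plants as synth
from phenoshoot.errors import (
    InsufficientJunctionsError,
    InsufficientPointsError,
    UndefinedChordError,
)

PARABOLA_ARC_01 = math.sqrt(5) / 2 + math.asinh(2) / 4  # 1.47894...


def geometry_from_function(f, a, b, n=101, rank=1):
    x = np.linspace(a, b, n)
    path = np.column_stack([x, f(x)])
    geom = comp.LeafGeometry(
        leaf_rank=rank, junction=tuple(path[0]), tip=tuple(path[-1]), path=path
    )
    geom.curve = comp.fit_leaf_curve(path)
    return geom


class TestFitLeafCurve:
    def test_collinear_points_order_one(self):
        path = np.column_stack([np.arange(10.0), 2 * np.arange(10.0) + 1])
        fit = comp.fit_leaf_curve(path, max_order=1)
        assert fit.order == 1
        assert fit.rms_residual == pytest.approx(0.0, abs=1e-9)

    def test_exact_parabola_recovered(self):
        x = np.linspace(-1, 1, 31)
        fit = comp.fit_leaf_curve(np.column_stack([x, x**2]))
        assert fit.rms_residual == pytest.approx(0.0, abs=1e-8)
        assert fit(0.5) == pytest.approx(0.25, abs=1e-8)

    def test_near_vertical_path_flips_orientation(self):
        y = np.linspace(0, 50, 60)
        path = np.column_stack([0.02 * y**1.5 / 7, y])
        fit = comp.fit_leaf_curve(path)
        assert fit.orientation == comp.YX
        forced = comp.fit_leaf_curve(path, orientation=comp.XY)
        assert fit.rms_residual <= forced.rms_residual

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientPointsError):
            comp.fit_leaf_curve(np.zeros((2, 2)))


class TestLeafLength:
    def test_straight_leaf_is_chord(self):
        geom = geometry_from_function(lambda x: 4 * x / 3, 0, 3)
        assert comp.leaf_length(geom) == pytest.approx(5.0, rel=1e-6)

    def test_parabola_closed_form(self):
        geom = geometry_from_function(lambda x: x**2, 0, 1)
        assert comp.leaf_length(geom) == pytest.approx(PARABOLA_ARC_01, abs=1e-4)

    def test_homogeneity_under_doubling(self):
        g1 = geometry_from_function(lambda x: x**2 / 10, 0, 10)
        g2 = geometry_from_function(lambda x: x**2 / 20, 0, 20)
        assert comp.leaf_length(g2) == pytest.approx(2 * comp.leaf_length(g1),
                                                     rel=1e-6)


class TestJunctionTipDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [((0, 0), (3, 4), 5.0), ((2, 2), (2, 2), 0.0), ((1, 1), (4, 5), 5.0)],
    )
    def test_euclidean(self, a, b, expected):
        assert comp.junction_tip_distance(a, b) == expected


class TestCurvature:
    def test_line_zero_everywhere(self):
        fit = comp.fit_leaf_curve(
            np.column_stack([np.arange(10.0), 3 * np.arange(10.0)]), max_order=1
        )
        for x in (-5, 0, 7.3):
            assert comp.curvature_at(fit, x) == 0.0
        assert comp.radius_of_curvature(fit, 0.0) == math.inf

    def test_parabola_at_origin(self):
        x = np.linspace(-1, 1, 41)
        fit = comp.fit_leaf_curve(np.column_stack([x, x**2]), max_order=2)
        assert comp.curvature_at(fit, 0.0) == pytest.approx(2.0, abs=1e-8)
        assert comp.radius_of_curvature(fit, 0.0) == pytest.approx(0.5, abs=1e-8)

    def test_semicircle_apex(self):
        theta = np.linspace(0.55, math.pi - 0.55, 80)
        x, y = 50 * np.cos(theta), 50 * np.sin(theta)
        fit = comp.fit_leaf_curve(np.column_stack([x, y]))
        assert comp.curvature_at(fit, 0.0) == pytest.approx(1 / 50, rel=0.10)


class TestApexAndMidLeaf:
    def test_symmetric_arch_apex_mid_chord(self):
        geom = geometry_from_function(lambda x: x * (1 - x), 0, 1)
        apex = comp.leaf_apex(geom)
        assert not apex.degenerate
        assert np.allclose(apex.points[:, 0], 0.5, atol=0.01)

    def test_straight_leaf_degenerate(self):
        geom = geometry_from_function(lambda x: 2 * x, 0, 5)
        apex = comp.leaf_apex(geom)
        assert apex.degenerate
        assert len(apex.points) == geom.n_points

    def test_two_equal_humps_two_apexes(self):
        geom = geometry_from_function(lambda x: np.sin(2 * math.pi * x), 0, 1,
                                      n=201)
        apex = comp.leaf_apex(geom)
        xs = sorted(apex.points[:, 0])
        assert len(xs) == 2
        assert xs[0] == pytest.approx(0.25, abs=0.01)
        assert xs[1] == pytest.approx(0.75, abs=0.01)

    def test_coincident_chord_rejected(self):
        path = np.column_stack([np.cos(np.linspace(0, 2 * np.pi, 20)),
                                np.sin(np.linspace(0, 2 * np.pi, 20))])
        geom = comp.LeafGeometry(1, tuple(path[0]), tuple(path[0]), path)
        geom.curve = comp.fit_leaf_curve(path)
        with pytest.raises(UndefinedChordError):
            comp.leaf_apex(geom)

    @pytest.mark.parametrize("n,b", [(10, 5), (7, 3), (1, 1)])
    def test_mid_leaf_index(self, n, b):
        assert max(1, n // 2) == b

    def test_mid_leaf_point_on_curve(self):
        geom = geometry_from_function(lambda x: x**2, 0, 1, n=10)
        x_mid, y_mid = comp.mid_leaf(geom)
        # 5th point (1-based) of 10 equally spaced abscissae on [0, 1]
        assert x_mid == pytest.approx(4 / 9, abs=1e-9)
        assert y_mid == pytest.approx((4 / 9) ** 2, abs=1e-6)

    def test_mid_leaf_curvature_methods_agree(self):
        geom = geometry_from_function(lambda x: x**2 / 200, 0, 60, n=61)
        analytic = comp.mid_leaf_curvature(geom, method="analytic")
        fd = comp.mid_leaf_curvature(geom, method="finite_difference")
        true_k = (2 / 200) / (1 + (2 * 29 / 200) ** 2) ** 1.5
        assert analytic == pytest.approx(true_k, rel=1e-3)
        assert fd == pytest.approx(analytic, rel=0.05)


class TestLeafJunctionAngle:
    @pytest.mark.parametrize(
        "m1,m2,expected",
        [(1, 0, math.pi / 4), (1, 1, 0.0), (1, -1, math.pi / 2),
         (0, math.inf, math.pi / 2)],
    )
    def test_slope_arithmetic(self, m1, m2, expected):
        assert comp.angle_between_slopes(m1, m2) == pytest.approx(expected)

    def test_angle_in_range_on_synthetic_leaf(self, day20_graph):
        for geom in comp.leaf_geometries(day20_graph):
            theta = comp.leaf_junction_angle(geom)
            assert 0 <= theta <= math.pi / 2


class TestIntegralArea:
    def test_straight_leaf_zero(self):
        geom = geometry_from_function(lambda x: 3 * x, 0, 2)
        assert comp.integral_leaf_skeleton_area(geom) == pytest.approx(
            0.0, abs=1e-9)

    def test_parabola_closed_form(self):
        geom = geometry_from_function(lambda x: x * (1 - x), 0, 1)
        assert comp.integral_leaf_skeleton_area(geom) == pytest.approx(
            1 / 6, abs=1e-6)

    def test_quadratic_scaling(self):
        g1 = geometry_from_function(lambda x: x * (10 - x) / 10, 0, 10)
        g2 = geometry_from_function(lambda x: x * (30 - x) / 30, 0, 30)
        a1 = comp.integral_leaf_skeleton_area(g1)
        a2 = comp.integral_leaf_skeleton_area(g2)
        assert a2 == pytest.approx(9 * a1, rel=1e-6)


class TestStemAngle:
    def test_vertical_stem_zero(self):
        junctions = [(50, y) for y in (10, 40, 70, 100)]
        assert comp.stem_angle(junctions) == pytest.approx(0.0, abs=1e-12)

    def test_45_degree_stem(self):
        junctions = [(y, y) for y in (10, 40, 70, 100)]
        assert comp.stem_angle(junctions) == pytest.approx(math.pi / 4)

    def test_noisy_tilt_recovered(self):
        rng = np.random.default_rng(0)
        tilt = 0.1
        y = np.linspace(0, 300, 12)
        x = 100 + math.tan(tilt) * y + rng.uniform(-1, 1, len(y))
        phi = comp.stem_angle(np.column_stack([x, y]))
        assert phi == pytest.approx(tilt, abs=0.02)

    def test_too_few_junctions_rejected(self):
        with pytest.raises(InsufficientJunctionsError):
            comp.stem_angle([(0, 0)])


class TestSyntheticRecovery:
    """Detected leaf geometry vs the generator's closed-form truth."""

    def test_arc_at_least_chord(self, day20_graph):
        for geom in comp.leaf_geometries(day20_graph):
            arc = comp.leaf_length(geom)
            chord = comp.junction_tip_distance(geom.junction, geom.tip)
            assert arc >= chord * (1 - 1e-6)

    def test_rotation_robustness(self):
        leaf = synth.LeafSpec(1, "right", 40.0, 20.0, 100.0, 0.003, 0.2,
                              base_angle=0.4)
        pts = synth.leaf_polyline(leaf, 90.0, n=120)
        rot = pts[:, ::-1] * np.array([1, -1])  # rotate 90 degrees
        g1 = comp.LeafGeometry(1, tuple(pts[0]), tuple(pts[-1]), pts)
        g1.curve = comp.fit_leaf_curve(pts)
        g2 = comp.LeafGeometry(1, tuple(rot[0]), tuple(rot[-1]), rot)
        g2.curve = comp.fit_leaf_curve(rot)
        assert g1.curve.orientation != g2.curve.orientation
        l1, l2 = comp.leaf_length(g1), comp.leaf_length(g2)
        assert abs(l1 - l2) / l1 < 0.01

    def test_length_and_area_vs_analytic_truth(self, plant_spec):
        """Mature rendered leaves: every length within 5% of the analytic
        truth; enclosed areas within 10% in the median (the area is
        chord-referenced, so a single borderline collar estimate can move
        an individual leaf further)."""
        from phenoshoot import gt_eval

        bg = synth.render_background(plant_spec)
        frame = synth.render_frame(plant_spec, 20)
        mask = seg.segment(frame.rgb, bg)
        graph = sg.mask_to_graph(mask)
        records = sg.leaf_edges(graph)
        _, _, pairs = gt_eval.match_leaves(graph, frame.truth, radius=15)
        truth = {lt.rank: lt for lt in frame.leaf_truth}
        trim = comp.JUNCTION_TRIM_FACTOR * graph.stroke_radius
        _, stem_path = sg.extract_stem(graph)
        stem_xy = np.array([(c, r) for (r, c) in stem_path], dtype=float)
        toprow = min(rec["junction"][0] for rec in records)
        area_errors = []
        for det_i, leaf_id in pairs:
            lt = truth[leaf_id]
            rec = records[det_i]
            if lt.length < 60 or rec["junction"][0] == toprow:
                continue  # skip young leaves and the unresolved whorl top
            geom = comp.leaf_geometry_from_record(rec, junction_trim=trim)
            comp.anchor_to_stem(geom, stem_xy)
            assert comp.leaf_length(geom) == pytest.approx(lt.length, rel=0.05)
            area = comp.integral_leaf_skeleton_area(geom)
            area_errors.append(abs(area - lt.enclosed_area) / lt.enclosed_area)
        assert len(area_errors) >= 3
        assert np.median(area_errors) <= 0.10
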