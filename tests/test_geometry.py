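"""Core ray-fan geometry: angles, origin placement, ray casting, leveling, eligibility."""

import math

import numpy as np
import pytest

import sinustd as st
from sinustd.errors import ConfigurationError, EligibilityError, FormatError, GeometryError

from _oracles import brute_ray_distances, ellipse_polar_radius
from conftest import semicircle_arc


class TestRayAngles:
    def test_default_fan_is_59_angles_3_to_177(self):
        angles = st.ray_angles()
        assert len(angles) == 59
        assert angles[0] == 3.0 and angles[-1] == 177.0
        assert np.allclose(np.diff(angles), 3.0)

    def test_count_matches_exhaustive_enumeration(self):
        enumerated = [a for a in range(1, 180) if a % 3 == 0]
        assert st.ray_angles(3, 3, 177) == [float(a) for a in enumerated]

    def test_single_element_sequence(self):
        assert st.ray_angles(90, 3, 90) == [90.0]

    @pytest.mark.parametrize("start,step,end", [
        (0.0, 3.0, 177.0),      # 0 degrees not allowed
        (3.0, 3.0, 180.0),      # 180 degrees not allowed
        (3.0, 3.0, 178.0),      # range not divisible by step
        (3.0, -1.0, 177.0),     # nonpositive step
        (90.0, 3.0, 60.0),      # start > end
    ])
    def test_invalid_configurations_rejected(self, start, step, end):
        with pytest.raises(ConfigurationError):
            st.ray_angles(start, step, end)


class TestPlaceOrigin:
    def test_vertical_midline_centred(self):
        baseline = st.BaselineSpec(st.Point2D(-10, 0), st.Point2D(10, 0))
        spec = st.place_origin(st.Point2D(0, -5), st.Point2D(0, 5), baseline)
        assert spec.origin == st.Point2D(0.0, 0.0)
        assert spec.right_baseline_RB == pytest.approx(10.0)
        assert st.midline_ratio(spec) == pytest.approx(0.5)

    def test_oblique_midline_analytic_intersection(self):
        baseline = st.BaselineSpec(st.Point2D(-8, 0), st.Point2D(12, 0))
        spec = st.place_origin(st.Point2D(1, 0), st.Point2D(2, 10), baseline)
        assert spec.origin.x == pytest.approx(1.0)
        assert spec.origin.y == pytest.approx(0.0)
        assert spec.right_baseline_RB == pytest.approx(11.0)
        assert spec.midline_ratio_r == pytest.approx(0.55)

    def test_parallel_midline_rejected(self):
        baseline = st.BaselineSpec(st.Point2D(-10, 0), st.Point2D(10, 0))
        with pytest.raises(GeometryError):
            st.place_origin(st.Point2D(0, 5), st.Point2D(1, 5), baseline)

    def test_intersection_outside_segment_rejected(self):
        baseline = st.BaselineSpec(st.Point2D(-10, 0), st.Point2D(10, 0))
        with pytest.raises(GeometryError):
            st.place_origin(st.Point2D(15, -5), st.Point2D(15, 5), baseline)

    def test_midline_ratio_scale_invariant(self):
        for c in (0.5, 3.7):
            baseline = st.BaselineSpec(st.Point2D(-8 * c, 0), st.Point2D(12 * c, 0))
            spec = st.place_origin(st.Point2D(c, 0), st.Point2D(2 * c, 10 * c), baseline)
            assert spec.midline_ratio_r == pytest.approx(0.55)

    def test_origin_at_right_terminus_gives_zero_ratio(self):
        baseline = st.BaselineSpec(st.Point2D(0, 0), st.Point2D(20, 0))
        spec = st.OriginSpec.from_origin(st.Point2D(20, 0), baseline)
        assert st.midline_ratio(spec) == 0.0


class TestCastRay:
    def test_semicircle_single_crossing(self):
        arc = semicircle_arc(radius=20.0)
        m = st.cast_ray(st.Point2D(0, 0), 90.0, arc)
        assert m.line_length_L == pytest.approx(20.0, abs=1e-9)
        assert m.n_crossings == 1
        assert not m.outermost_used

    def test_w_shaped_arc_uses_outermost_crossing(self):
        # crosses the vertical ray at y=14 (proper crossing) and touches it at
        # the vertex (0, 8); the vertex hit is merged into one crossing
        arc = st.SinusOutline.from_coords(
            [(-10, 0), (-2, 14), (2, 14), (0, 8), (3, 9), (10, 0)], id="w")
        m = st.cast_ray(st.Point2D(0, 0), 90.0, arc)
        assert m.line_length_L == pytest.approx(14.0, abs=1e-9)
        assert m.n_crossings == 2
        assert m.outermost_used
        oracle = brute_ray_distances((0, 0), 90.0, arc.as_array())
        assert oracle == pytest.approx([8.0, 14.0], abs=1e-9)

    def test_rectangle_arc_diagonal_hits_corner(self):
        arc = st.SinusOutline.from_coords([(-10, 0), (-10, 10), (10, 10), (10, 0)], id="rect")
        m = st.cast_ray(st.Point2D(0, 0), 45.0, arc)
        assert m.line_length_L == pytest.approx(10.0 * math.sqrt(2.0), abs=1e-9)

    def test_missing_intersection_reports_angle(self):
        arc = st.SinusOutline.from_coords([(-10, 0), (-5, 5), (-2, 0.5)], id="offside")
        with pytest.raises(GeometryError, match="90"):
            st.cast_ray(st.Point2D(0, 0), 90.0, arc)

    @pytest.mark.parametrize("theta", [0.0, 180.0, -5.0, 200.0])
    def test_angles_outside_open_interval_rejected(self, theta):
        arc = semicircle_arc()
        with pytest.raises(ConfigurationError):
            st.cast_ray(st.Point2D(0, 0), theta, arc)

    def test_outermost_matches_brute_force_on_random_outlines(self):
        rng = np.random.default_rng(7)
        for seed in rng.integers(0, 2**31, size=50):
            outline, baseline, origin = st.generate_outline(seed=int(seed))
            verts = outline.as_array()
            o = (origin.origin.x, origin.origin.y)
            for theta in rng.choice(st.ray_angles(), size=6, replace=False):
                m = st.cast_ray(origin.origin, float(theta), outline)
                oracle = brute_ray_distances(o, float(theta), verts)
                assert m.line_length_L == pytest.approx(max(oracle), rel=1e-9)
                assert m.n_crossings == len(oracle)


class TestMeasureProfile:
    def test_semicircle_profile_is_constant_radius(self):
        arc = semicircle_arc(radius=17.5)
        baseline = st.BaselineSpec(st.Point2D(-17.5, 0), st.Point2D(17.5, 0))
        origin = st.OriginSpec.from_origin(st.Point2D(0, 0), baseline)
        profile = st.measure_profile(arc, baseline, origin)
        assert len(profile.measurements) == 59
        assert np.allclose(profile.lengths, 17.5, atol=1e-6)

    def test_half_ellipse_matches_closed_form(self):
        a, b = 30.0, 18.0
        t = np.linspace(np.pi, 0.0, 4001)
        arc = st.SinusOutline.from_coords(
            np.column_stack([a * np.cos(t), b * np.sin(t)]), id="ellipse")
        baseline = st.BaselineSpec(st.Point2D(-a, 0), st.Point2D(a, 0))
        origin = st.OriginSpec.from_origin(st.Point2D(0, 0), baseline)
        profile = st.measure_profile(arc, baseline, origin)
        expected = np.array([ellipse_polar_radius(a, b, th) for th in profile.angles])
        assert np.allclose(profile.lengths, expected, rtol=1e-6)

    def test_every_eligible_outline_yields_59_measurements(self, standard_profile):
        assert len(standard_profile.measurements) == 59
        assert np.allclose(standard_profile.angles, st.ray_angles())

    def test_custom_angle_subset(self, standard_outline):
        outline, baseline, origin = standard_outline
        profile = st.measure_profile(outline, baseline, origin, angles=[30, 90, 150])
        assert list(profile.angles) == [30.0, 90.0, 150.0]


class TestLineLengthFromPerimeter:
    @pytest.mark.parametrize("P,RB,expected", [(10.0, 10.0, 0.0), (30.0, 10.0, 20.0)])
    def test_subtraction(self, P, RB, expected):
        assert st.line_length_from_perimeter(P, RB) == pytest.approx(expected)

    def test_inconsistent_export_rejected(self):
        with pytest.raises(FormatError):
            st.line_length_from_perimeter(5.0, 10.0)

    def test_consistency_with_cast_ray(self, standard_outline, standard_profile):
        RB = standard_profile.origin.right_baseline_RB
        for m in standard_profile.measurements[::10]:
            P = RB + m.line_length_L
            assert st.line_length_from_perimeter(P, RB) == pytest.approx(
                m.line_length_L, abs=1e-9)


class TestRotateToLevel:
    def test_identity_rotation_preserves_coordinates(self, standard_outline):
        outline, baseline, origin = standard_outline
        out2, base2, _ = st.rotate_to_level(outline, baseline, origin, angle_deg=0.0)
        assert np.allclose(out2.as_array(), outline.as_array())
        assert base2.tilt_deg == pytest.approx(0.0, abs=1e-12)

    def test_leveling_a_tilted_baseline(self, standard_outline):
        outline, baseline, origin = standard_outline
        tilted = st.rotate_to_level(outline, baseline, origin, angle_deg=5.0)
        assert tilted[1].tilt_deg == pytest.approx(5.0, abs=1e-9)
        level = st.rotate_to_level(*tilted)
        assert level[1].tilt_deg == pytest.approx(0.0, abs=1e-9)

    def test_profile_invariant_under_leveling(self, standard_outline, standard_profile):
        outline, baseline, origin = standard_outline
        tilted = st.rotate_to_level(outline, baseline, origin, angle_deg=-11.25)
        profile_tilted = st.measure_profile(*tilted)
        assert np.allclose(profile_tilted.lengths, standard_profile.lengths, rtol=1e-9)
        assert profile_tilted.baseline.length_B == pytest.approx(
            baseline.length_B, rel=1e-12)


class TestEligibility:
    def test_arc_below_baseline_flagged(self):
        arc = st.SinusOutline.from_coords([(-10, 0), (0, -8), (10, 0)], id="below")
        baseline = st.BaselineSpec(st.Point2D(-10, 0), st.Point2D(10, 0))
        origin = st.OriginSpec.from_origin(st.Point2D(0, 0), baseline)
        report = st.check_eligibility(arc, baseline, origin)
        assert not report.above_baseline
        assert not report.eligible

    def test_origin_outside_termini_flagged(self):
        arc = semicircle_arc(radius=10.0)
        baseline = st.BaselineSpec(st.Point2D(-10, 0), st.Point2D(10, 0))
        origin = st.OriginSpec.from_origin(st.Point2D(10, 0), baseline)
        report = st.check_eligibility(arc, baseline, origin)
        assert not report.origin_interior

    def test_unanchored_arc_flagged(self):
        arc = st.SinusOutline.from_coords([(-7, 0), (0, 9), (7, 0)], id="short")
        baseline = st.BaselineSpec(st.Point2D(-10, 0), st.Point2D(10, 0))
        origin = st.OriginSpec.from_origin(st.Point2D(0, 0), baseline)
        report = st.check_eligibility(arc, baseline, origin)
        assert not report.arc_continuous

    def test_ineligible_outline_cannot_be_measured(self):
        arc = st.SinusOutline.from_coords([(-10, 0), (0, -8), (10, 0)], id="below")
        baseline = st.BaselineSpec(st.Point2D(-10, 0), st.Point2D(10, 0))
        origin = st.OriginSpec.from_origin(st.Point2D(0, 0), baseline)
        with pytest.raises(EligibilityError):
            st.measure_profile(arc, baseline, origin)

    def test_standard_synthetic_outline_is_eligible(self, standard_outline):
        outline, baseline, origin = standard_outline
        assert st.check_eligibility(outline, baseline, origin).eligible


class TestInvariances:
    def test_scale_equivariance(self, standard_outline, standard_profile):
        outline, baseline, origin = standard_outline
        c = 2.7
        scaled_outline = st.SinusOutline.from_coords(outline.as_array() * c, id=outline.id)
        scaled_baseline = st.BaselineSpec(
            st.Point2D(baseline.left_terminus.x * c, baseline.left_terminus.y * c),
            st.Point2D(baseline.right_terminus.x * c, baseline.right_terminus.y * c))
        scaled_origin = st.OriginSpec.from_origin(
            st.Point2D(origin.origin.x * c, origin.origin.y * c), scaled_baseline)
        scaled = st.measure_profile(scaled_outline, scaled_baseline, scaled_origin)
        assert np.allclose(scaled.lengths, c * standard_profile.lengths, rtol=1e-9)
        assert scaled_baseline.length_B == pytest.approx(c * baseline.length_B, rel=1e-12)
        assert scaled_origin.midline_ratio_r == pytest.approx(
            origin.midline_ratio_r, rel=1e-12)
        s0 = st.standardize_profile(standard_profile).values()
        s1 = st.standardize_profile(scaled).values()
        assert np.allclose(s0, s1, atol=1e-12)

    def test_rigid_motion_invariance(self, standard_outline, standard_profile):
        outline, baseline, origin = standard_outline
        th = math.radians(33.0)
        rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        shift = np.array([12.3, -4.5])

        def move(xy):
            return (np.asarray(xy) @ rot.T) + shift

        m_outline = st.SinusOutline.from_coords(move(outline.as_array()), id=outline.id)
        m_baseline = st.BaselineSpec(
            st.Point2D(*move(baseline.left_terminus.as_array())),
            st.Point2D(*move(baseline.right_terminus.as_array())))
        m_origin = st.OriginSpec.from_origin(
            st.Point2D(*move(origin.origin.as_array())), m_baseline)
        moved = st.measure_profile(m_outline, m_baseline, m_origin)
        assert np.allclose(moved.lengths, standard_profile.lengths, rtol=1e-9)
        assert m_origin.midline_ratio_r == pytest.approx(origin.midline_ratio_r, rel=1e-9)
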