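"""Geometry pipeline: areas, profiles, lengths, volumes, shape factors."""

import numpy as np
import pytest
import shapely.geometry as sgeom
from hypothesis import given, settings, strategies as st

import musclemorph as mm
from musclemorph.errors import DegenerateGeometryError, ValidationError
from musclemorph.geometry import (
    ACSAProfile,
    acsa_profile,
    find_acsa_max,
    integrate_volume,
    measure_morphology,
    muscle_length,
    polygon_area,
)
from musclemorph.synthetic import AnalyticSolidSpec, make_analytic_solid


def fan_triangulation_area(vertices):
    """Independent oracle: sum of signed triangle areas fanned from vertex 0."""
    v = np.asarray(vertices, float)
    total = 0.0
    for i in range(1, len(v) - 1):
        a, b, c = v[0], v[i], v[i + 1]
        total += 0.5 * ((b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1]))
    return abs(total)


def star_polygon(rng, n):
    """Random star-shaped (hence simple) polygon around the origin."""
    theta = np.sort(rng.uniform(0, 2 * np.pi, n))
    r = rng.uniform(1.0, 10.0, n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


class TestPolygonArea:
    @pytest.mark.parametrize(
        "vertices,expected",
        [
            ([(0, 0), (10, 0), (10, 10), (0, 10)], 100.0),
            ([(0, 0), (40, 0), (0, 30)], 600.0),
        ],
    )
    def test_hand_examples(self, vertices, expected):
        assert polygon_area(vertices) == pytest.approx(expected)

    def test_orientation_independent(self):
        sq = np.array([(0, 0), (10, 0), (10, 10), (0, 10)], float)
        assert polygon_area(sq) == polygon_area(sq[::-1])

    def test_random_simple_polygon_matches_triangulation_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            poly = star_polygon(rng, 50)
            assert polygon_area(poly) == pytest.approx(fan_triangulation_area(poly))
            assert polygon_area(poly) == pytest.approx(sgeom.Polygon(poly).area)

    @pytest.mark.parametrize(
        "bad", [[(0, 0), (1, 1)], [(0, 0), (1, 1), (2, 2)]],
        ids=["two-vertices", "collinear"],
    )
    def test_degenerate_rejected(self, bad):
        with pytest.raises(DegenerateGeometryError):
            polygon_area(bad)

    @settings(derandomize=True, max_examples=30)
    @given(scale=st.floats(0.1, 50), n=st.integers(4, 30), seed=st.integers(0, 1000))
    def test_scaling_multiplies_area_by_square(self, scale, n, seed):
        poly = star_polygon(np.random.default_rng(seed), n)
        assert polygon_area(scale * poly) == pytest.approx(
            scale**2 * polygon_area(poly), rel=1e-9
        )


class TestACSAProfile:
    def test_cylinder_constant_profile(self):
        stack = make_analytic_solid(AnalyticSolidSpec("cylinder", 10.0, 100.0, 10.0))
        prof = acsa_profile(stack)
        assert prof.acsa == pytest.approx(np.full(11, 100 * np.pi))

    def test_two_outer_polygons_sum(self):
        sq50 = np.array([(0, 0), (10, 0), (10, 5), (0, 5)], float)
        sq30 = np.array([(20, 0), (26, 0), (26, 5), (20, 5)], float)
        stack = mm.ContourStack(
            muscle_label="GM",
            contours=[
                mm.Contour(0.0, sq50), mm.Contour(0.0, sq30),
                mm.Contour(2.0, sq50), mm.Contour(2.0, sq30),
            ],
            slice_positions=np.array([0.0, 2.0]),
        )
        assert acsa_profile(stack).acsa == pytest.approx([80.0, 80.0])

    def test_hole_subtracted_and_excess_hole_rejected(self):
        outer = np.array([(0, 0), (10, 0), (10, 10), (0, 10)], float)
        hole = np.array([(4, 4), (6, 4), (6, 6), (4, 6)], float)
        stack = mm.ContourStack(
            "GM",
            [mm.Contour(0.0, outer), mm.Contour(0.0, hole, role="hole")],
            np.array([0.0]),
        )
        assert acsa_profile(stack).acsa == pytest.approx([96.0])
        bad = mm.ContourStack(
            "GM",
            [mm.Contour(0.0, hole), mm.Contour(0.0, outer, role="hole")],
            np.array([0.0]),
        )
        with pytest.raises(ValidationError):
            acsa_profile(bad)

    def test_spheroid_sections_match_analytic_ellipse_area(self):
        # prolate spheroid: A(z) = pi*a*b*(1 - (z/c)^2) with z from the centre
        a = b = 20.0
        c = 150.0
        stack = make_analytic_solid(AnalyticSolidSpec("spheroid", a, 2 * c, 2.0))
        prof = acsa_profile(stack)
        zc = prof.z - c
        inner = np.abs(zc) < 0.9 * c  # away from the poles
        analytic = np.pi * a * b * (1 - (zc[inner] / c) ** 2)
        assert prof.acsa[inner] == pytest.approx(analytic, rel=0.01)


class TestLengthAndVolume:
    def test_length_every_2mm(self):
        z = np.arange(0.0, 309.0, 2.0)
        prof = ACSAProfile(z=z, acsa=np.ones_like(z))
        assert muscle_length(prof) == pytest.approx(30.8)

    def test_non_uniform_grid(self):
        prof = ACSAProfile(z=[0.0, 5.0, 17.0], acsa=[1.0, 1.0, 1.0])
        assert muscle_length(prof) == pytest.approx(1.7)

    def test_translation_invariance(self):
        z = np.array([0.0, 5.0, 17.0])
        a = np.array([3.0, 4.0, 5.0])
        p1 = ACSAProfile(z=z, acsa=a)
        p2 = ACSAProfile(z=z + 100.0, acsa=a)
        assert muscle_length(p1) == muscle_length(p2)
        assert integrate_volume(p1) == pytest.approx(integrate_volume(p2))

    def test_single_slice_errors(self):
        prof = ACSAProfile(z=[0.0], acsa=[1.0])
        with pytest.raises(ValidationError):
            muscle_length(prof)
        with pytest.raises(ValidationError):
            integrate_volume(prof)

    def test_constant_profile_volume(self):
        z = np.arange(0.0, 101.0, 2.0)
        prof = ACSAProfile(z=z, acsa=np.full_like(z, 500.0))
        assert integrate_volume(prof) == pytest.approx(50.0)

    def test_cone_volume_against_analytic(self):
        stack = make_analytic_solid(
            AnalyticSolidSpec("cone", np.sqrt(2400 / np.pi), 300.0, 2.0)
        )
        v = integrate_volume(acsa_profile(stack))
        assert v == pytest.approx(240.0, rel=1e-3)

    def test_spheroid_volume_against_analytic(self):
        a = 20.0
        c = 125.0
        stack = make_analytic_solid(AnalyticSolidSpec("spheroid", a, 2 * c, 2.0))
        v = integrate_volume(acsa_profile(stack))
        assert v == pytest.approx(4 / 3 * np.pi * a * a * c / 1000.0, rel=5e-3)

    def test_trapezoid_error_shrinks_quadratically(self):
        # halving h should cut the volume error by ~4 for a smooth profile
        a, c = 20.0, 125.0
        exact = 4 / 3 * np.pi * a * a * c / 1000.0
        errors = []
        for h in (4.0, 2.0, 1.0):
            stack = make_analytic_solid(AnalyticSolidSpec("spheroid", a, 2 * c, h))
            errors.append(abs(integrate_volume(acsa_profile(stack)) - exact))
        assert errors[0] > errors[1] > errors[2]
        assert errors[0] / errors[1] == pytest.approx(4.0, rel=0.5)
        assert errors[1] / errors[2] == pytest.approx(4.0, rel=0.5)


class TestFindACSAMax:
    def test_monotone_profile_peaks_at_proximal_end(self):
        z = np.arange(0.0, 101.0, 10.0)
        prof = ACSAProfile(z=z, acsa=z + 1.0, shank_landmarks=(0.0, 200.0))
        amax, pos = find_acsa_max(prof)
        assert amax == pytest.approx(1.01)  # 101 mm^2 in cm^2
        assert pos == pytest.approx(50.0)

    def test_tie_resolves_to_most_distal(self):
        prof = ACSAProfile(
            z=[0.0, 10.0, 20.0], acsa=[1.0, 5.0, 5.0], shank_landmarks=(0.0, 100.0)
        )
        _, pos = find_acsa_max(prof)
        assert pos == pytest.approx(10.0)

    def test_missing_landmarks_error(self):
        prof = ACSAProfile(z=[0.0, 1.0], acsa=[1.0, 2.0])
        with pytest.raises(ValidationError):
            find_acsa_max(prof)

    def test_constructed_peak_recovered_within_half_slice(self):
        spec = mm.ParametricMuscleSpec(
            l_muscle_cm=30.0, acsa_max_cm2=20.0, shape_factor_target=0.55,
            peak_relative=0.6, muscle_offset_mm=36.0, slice_spacing_mm=2.0,
        )
        stack = mm.make_parametric_muscle(spec, "S1", "SOL")
        # mode at 36 + 0.6*300 = 216 mm -> 60 % of the 360 mm shank
        _, pos = find_acsa_max(acsa_profile(stack))
        assert abs(pos - 60.0) <= 100.0 * 1.0 / 360.0  # half a slice spacing


class TestMeasureMorphology:
    def test_cylinder_shape_factor_exactly_one(self):
        stack = make_analytic_solid(AnalyticSolidSpec("cylinder", 10.0, 100.0, 2.0))
        m = measure_morphology(stack)
        assert m.shape_factor == pytest.approx(1.0, abs=1e-12)

    def test_cone_limit_one_third(self):
        errs = []
        for h in (4.0, 1.0):
            stack = make_analytic_solid(
                AnalyticSolidSpec("cone", np.sqrt(2400 / np.pi), 300.0, h)
            )
            errs.append(abs(measure_morphology(stack).shape_factor - 1 / 3))
        assert errs[-1] < 0.005 / 3
        assert errs[1] < errs[0]

    def test_spheroid_limit_two_thirds(self):
        stack = make_analytic_solid(AnalyticSolidSpec("spheroid", 20.0, 250.0, 2.0))
        assert measure_morphology(stack).shape_factor == pytest.approx(2 / 3, rel=0.005)

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(
        scale=st.floats(0.5, 3.0),
        p=st.floats(0.35, 0.9),
        mode=st.floats(0.25, 0.75),
    )
    def test_scale_equivariance_and_factor_bound(self, scale, p, mode):
        """Scaling coordinates by s: areas x s^2, volume x s^3, p invariant, p <= 1."""
        spec = mm.ParametricMuscleSpec(
            l_muscle_cm=25.0, acsa_max_cm2=15.0, shape_factor_target=p,
            peak_relative=mode, muscle_offset_mm=30.0,
        )
        stack = mm.make_parametric_muscle(spec, "S", "GM")
        m = measure_morphology(stack, validate=False)
        scaled = mm.ContourStack(
            muscle_label=stack.muscle_label,
            contours=[
                mm.Contour(c.z * scale, c.vertices * scale, c.role)
                for c in stack.contours
            ],
            slice_positions=stack.slice_positions * scale,
            shank_landmarks=(
                stack.shank_landmarks[0] * scale, stack.shank_landmarks[1] * scale
            ),
            subject_id=stack.subject_id,
        )
        ms = measure_morphology(scaled, validate=False)
        assert ms.acsa_max_cm2 == pytest.approx(m.acsa_max_cm2 * scale**2, rel=1e-9)
        assert ms.v_measured_cm3 == pytest.approx(m.v_measured_cm3 * scale**3, rel=1e-9)
        assert ms.l_muscle_cm == pytest.approx(m.l_muscle_cm * scale, rel=1e-9)
        assert ms.shape_factor == pytest.approx(m.shape_factor, rel=1e-9)
        assert ms.shape_factor <= 1.0

    def test_axial_stretch_leaves_shape_factor(self):
        stack = make_analytic_solid(AnalyticSolidSpec("spheroid", 20.0, 250.0, 2.0))
        m = measure_morphology(stack)
        k = 1.7
        stretched = mm.ContourStack(
            muscle_label=stack.muscle_label,
            contours=[mm.Contour(c.z * k, c.vertices, c.role) for c in stack.contours],
            slice_positions=stack.slice_positions * k,
            shank_landmarks=(0.0, 250.0 * k),
            subject_id=stack.subject_id,
        )
        ms = measure_morphology(stretched)
        assert ms.l_muscle_cm == pytest.approx(m.l_muscle_cm * k, rel=1e-9)
        assert ms.v_measured_cm3 == pytest.approx(m.v_measured_cm3 * k, rel=1e-9)
        assert ms.shape_factor == pytest.approx(m.shape_factor, rel=1e-9)
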