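import numpy as np
import pytest

from gpcochlea.geometry import (
    ContourStation,
    ModiolarAxis,
    STSegmentation,
    cross_section_area,
    extract_footprint,
    lateral_wall,
    section_centroid,
    volume_increments,
    volume_profile,
)

from conftest import rigid_transform

UNIT_SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
Z_AXIS = ModiolarAxis(origin=np.zeros(3), direction=np.array([0.0, 0.0, 1.0]),
                      rw_reference=np.array([1.0, 0.0, 0.0]))


def ellipse_polygon(n, a, b):
    phi = 2 * np.pi * np.arange(n) / n
    return np.column_stack([a * np.cos(phi), b * np.sin(phi)])


def embed(points2d, angle_deg=0.0, z0=0.0):
    """Place an (r, z) contour into the half-plane at the given azimuth."""
    radial = Z_AXIS.radial_direction(angle_deg)
    return (np.outer(points2d[:, 0], radial)
            + np.outer(points2d[:, 1] + z0, Z_AXIS.direction))


class TestCrossSectionArea:
    @pytest.mark.parametrize(
        "points,expected",
        [
            (UNIT_SQUARE, 1.0),
            (np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 1.0]]), 1.0),
            # closed form for a regular n-gon inscribed in an ellipse
            (ellipse_polygon(64, 0.5, 0.3), 0.5 * 64 * 0.5 * 0.3 * np.sin(2 * np.pi / 64)),
        ],
    )
    def test_known_polygons(self, points, expected):
        assert cross_section_area(points) == pytest.approx(expected, rel=1e-12)

    def test_ellipse_64gon_value(self):
        assert cross_section_area(ellipse_polygon(64, 0.5, 0.3)) == pytest.approx(
            0.47048, abs=5e-6)

    def test_rejects_too_few_points(self):
        with pytest.raises(ValueError):
            cross_section_area(np.array([[0.0, 0.0], [1.0, 0.0]]))

    def test_rejects_self_intersection(self):
        bowtie = np.array([[0.0, 0.0], [1.0, 1.0], [1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="self-intersect"):
            cross_section_area(bowtie)

    @pytest.mark.parametrize("seed", range(5))
    def test_rigid_invariance_and_orientation(self, seed):
        """Area is unchanged by 3-D rigid motion and by point-order reversal."""
        rng = np.random.default_rng(seed)
        # star-shaped polygon: strictly increasing angles, random radii
        ang = np.sort(rng.uniform(0, 2 * np.pi, 12))
        rad = rng.uniform(0.5, 2.0, 12)
        poly = np.column_stack([rad * np.cos(ang), rad * np.sin(ang), np.zeros(12)])
        ref = cross_section_area(poly)
        rot, t = rigid_transform(rng)
        moved = poly @ rot.T + t
        assert cross_section_area(moved) == pytest.approx(ref, rel=1e-9)
        assert cross_section_area(poly[::-1]) == pytest.approx(ref, rel=1e-12)


class TestSectionCentroid:
    def test_unit_square(self):
        assert section_centroid(UNIT_SQUARE) == pytest.approx([0.5, 0.5])

    def test_right_triangle(self):
        tri = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 3.0]])
        assert section_centroid(tri) == pytest.approx([1.0, 1.0])

    def test_l_shape_by_decomposition(self):
        hexa = np.array([[0, 0], [2, 0], [2, 1], [1, 1], [1, 2], [0, 2]], dtype=float)
        # two rectangles: 2×1 at (1, 0.5) and 1×1 at (0.5, 1.5)
        expected = (2 * np.array([1.0, 0.5]) + 1 * np.array([0.5, 1.5])) / 3
        assert section_centroid(hexa) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx([5 / 6, 5 / 6])

    def test_embedded_3d_round_trip(self):
        pts = embed(np.column_stack([ellipse_polygon(32, 0.4, 0.2)[:, 0] + 2.0,
                                     ellipse_polygon(32, 0.4, 0.2)[:, 1]]), 45.0, 1.0)
        c = section_centroid(pts)
        expected = 2.0 * Z_AXIS.radial_direction(45.0) + np.array([0, 0, 1.0])
        assert c == pytest.approx(expected, abs=1e-12)

    def test_degenerate_rejected(self):
        line = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            section_centroid(line)


class TestVolumeIncrements:
    def test_prism_between_equal_squares(self):
        """Two unit-area sections 1 mm apart enclose exactly 1 μL."""
        square = np.column_stack([UNIT_SQUARE[:, 0] + 2.0, UNIT_SQUARE[:, 1]])
        delta = np.rad2deg(2 * np.arcsin(0.5 / 2.5))  # centroid chord = 1 mm
        seg = STSegmentation(
            "prism", Z_AXIS,
            (ContourStation(0.0, embed(square, 0.0)),
             ContourStation(delta, embed(square, delta))),
        )
        prof = volume_profile(seg)
        assert prof.volumes == pytest.approx([0.0, 1.0], abs=1e-12)

    def test_cone_limit(self):
        """Area shrinking to (near) zero over 3 mm gives the cone volume Ah/3."""
        inc = volume_increments(np.array([1.0, 1e-18]), np.array([3.0]))
        assert inc[0] == pytest.approx(1.0, rel=1e-6)

    def test_linear_taper_matches_exact_frustum(self):
        """Frustum rule is exact for a cone sampled at any resolution."""
        x = np.arange(0.0, 10.0 + 1e-9, 0.5)
        r = 0.5 + (0.25 - 0.5) * x / 10.0
        total = volume_increments(np.pi * r ** 2, np.diff(x)).sum()
        exact = np.pi * 10.0 * (0.5 ** 2 + 0.5 * 0.25 + 0.25 ** 2) / 3.0
        assert total == pytest.approx(exact, rel=1e-12)
        assert total == pytest.approx(4.5815, abs=5e-5)

    def test_trapezoid_rule_never_below_frustum(self):
        rng = np.random.default_rng(0)
        areas = rng.uniform(0.1, 1.0, 20)
        d = rng.uniform(0.1, 1.0, 19)
        assert np.all(volume_increments(areas, d, "trapezoid")
                      >= volume_increments(areas, d, "frustum"))

    def test_non_monotone_angles_rejected(self):
        square = np.column_stack([UNIT_SQUARE[:, 0] + 2.0, UNIT_SQUARE[:, 1]])
        with pytest.raises(ValueError, match="increasing"):
            STSegmentation(
                "bad", Z_AXIS,
                (ContourStation(22.5, embed(square, 22.5)),
                 ContourStation(0.0, embed(square, 0.0))),
            )


class TestVolumeProfileOnSynthetic:
    def test_monotone_and_conserving(self, default_cochlea):
        seg, _ = default_cochlea
        prof = volume_profile(seg)
        assert np.all(np.diff(prof.volumes) >= 0)
        assert prof.volumes[0] == 0.0
        assert prof.total == pytest.approx(np.sum(np.diff(prof.volumes)))

    def test_agrees_with_quadrature_oracle(self, default_cochlea):
        """22.5° stations reproduce the fine-quadrature volume within 0.5%."""
        seg, truth = default_cochlea
        prof = volume_profile(seg)
        oracle = truth["volume_profile"](prof.angles[1:])
        rel = np.abs(prof.volumes[1:] - oracle) / oracle
        assert np.max(rel) < 0.005


class TestLateralWall:
    def test_circular_contour_offset_from_axis(self):
        circle = ellipse_polygon(36, 0.4, 0.4)
        pts = embed(np.column_stack([circle[:, 0] + 2.0, circle[:, 1]]), 0.0)
        seg = STSegmentation(
            "c", Z_AXIS,
            (ContourStation(0.0, pts), ContourStation(22.5, embed(
                np.column_stack([circle[:, 0] + 2.0, circle[:, 1]]), 22.5))),
        )
        wall = lateral_wall(seg)
        assert np.linalg.norm(wall.points[0][:2]) == pytest.approx(2.4, abs=1e-12)

    def test_unique_farthest_vertex_and_tie_break(self):
        # two vertices exactly at radius 3: indices 1 and 3 → first one wins
        quad = np.array([[2.0, 0.0], [3.0, 1.0], [2.0, 2.0], [3.0, -1.0]])
        pts = embed(quad, 0.0)
        seg = STSegmentation(
            "t", Z_AXIS,
            (ContourStation(0.0, pts), ContourStation(22.5, embed(quad, 22.5))),
        )
        wall = lateral_wall(seg)
        assert wall.points[0] == pytest.approx(pts[1])


class TestExtractFootprint:
    @staticmethod
    def _wall_from_radii(angles, radii):
        from gpcochlea.geometry import LateralWallProfile
        pts = np.array([r * Z_AXIS.radial_direction(a) for a, r in zip(angles, radii)])
        return LateralWallProfile(np.asarray(angles, float), pts)

    def test_circular_footprint(self):
        angles = np.arange(0.0, 360.1, 22.5)
        wall = self._wall_from_radii(angles, np.full(angles.size, 2.0))
        fp = extract_footprint(wall, Z_AXIS, warn_plausibility=False)
        assert fp.A == pytest.approx(4.0, abs=1e-12)
        assert fp.B == pytest.approx(4.0, abs=1e-12)

    def test_elliptical_footprint_rw_on_major_axis(self):
        angles = np.arange(0.0, 360.1, 22.5)
        t = np.deg2rad(angles)
        r = 2.0 * 1.4 / np.sqrt((1.4 * np.cos(t)) ** 2 + (2.0 * np.sin(t)) ** 2)
        fp = extract_footprint(self._wall_from_radii(angles, r), Z_AXIS,
                               warn_plausibility=False)
        assert fp.A == pytest.approx(4.0, abs=1e-9)
        assert fp.B == pytest.approx(2.8, abs=1e-9)
        assert fp.A >= fp.B

    def test_synthetic_ground_truth_recovery(self, footprint_cochlea):
        seg, truth = footprint_cochlea
        fp = extract_footprint(lateral_wall(seg), seg.axis, warn_plausibility=False)
        assert abs(fp.A / truth["A"] - 1) < 0.02
        assert abs(fp.B / truth["B"] - 1) < 0.02

    def test_rigid_transform_invariance(self, footprint_cochlea):
        seg, _ = footprint_cochlea
        fp0 = extract_footprint(lateral_wall(seg), seg.axis, warn_plausibility=False)
        rng = np.random.default_rng(3)
        rot, t = rigid_transform(rng)
        axis = ModiolarAxis(origin=seg.axis.origin @ rot.T + t,
                            direction=seg.axis.direction @ rot.T,
                            rw_reference=seg.axis.rw_reference @ rot.T + t)
        stations = tuple(
            ContourStation(s.angle, s.points @ rot.T + t) for s in seg.stations
        )
        moved = STSegmentation(seg.specimen_id, axis, stations)
        fp1 = extract_footprint(lateral_wall(moved), moved.axis,
                                warn_plausibility=False)
        assert fp1.A == pytest.approx(fp0.A, abs=1e-9)
        assert fp1.B == pytest.approx(fp0.B, abs=1e-9)

    def test_incomplete_basal_turn_rejected(self):
        angles = np.arange(0.0, 270.1, 22.5)
        wall = self._wall_from_radii(angles, np.full(angles.size, 2.0))
        with pytest.raises(ValueError, match="360"):
            extract_footprint(wall, Z_AXIS)
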