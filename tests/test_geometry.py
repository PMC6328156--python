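"""Geometry: ellipse fitting, ray casting, profile extraction, DDLS scalars."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pcdr import (
    CDRProfile,
    DiscSegmentation,
    Ellipse,
    LandmarkSet,
    canonical_orientation,
    extract_pcdr,
    fit_ellipse,
    orthogonal_residuals,
    ray_boundary_distance,
    rim_to_disc_narrowest,
    vertical_cdr,
    vertical_disc_size,
)
from pcdr.geometry import (
    EmptyProfileError,
    GeometryError,
    InsufficientLandmarksError,
    NonEllipseError,
    _ray_distance,
)

from oracles import polygon_ray_distance, polygon_vertical_chord, random_valid_segmentation


def ellipse_points(e: Ellipse, n: int, rng=None, noise=0.0) -> np.ndarray:
    t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    pts = np.column_stack([e.semi_major * np.cos(t), e.semi_minor * np.sin(t)])
    c, s = math.cos(e.rotation), math.sin(e.rotation)
    pts = pts @ np.array([[c, -s], [s, c]]).T + [e.center_x, e.center_y]
    if noise:
        pts = pts + rng.normal(0.0, noise, pts.shape)
    return pts


class TestFitEllipse:
    def test_exact_recovery(self):
        truth = Ellipse(100.0, 80.0, 60.0, 40.0, 0.3)
        fit = fit_ellipse(LandmarkSet("e1", "disc", ellipse_points(truth, 12)))
        for attr in ("center_x", "center_y", "semi_major", "semi_minor", "rotation"):
            assert getattr(fit, attr) == pytest.approx(getattr(truth, attr), rel=1e-6)
        assert orthogonal_residuals(fit, ellipse_points(truth, 12)).max() < 1e-6

    def test_five_points_on_circle(self):
        truth = Ellipse(0.0, 0.0, 50.0, 50.0, 0.0)
        fit = fit_ellipse(LandmarkSet("e1", "cup", ellipse_points(truth, 5)))
        assert fit.semi_major == pytest.approx(50.0, rel=1e-9)
        assert fit.semi_minor == pytest.approx(50.0, rel=1e-9)
        assert 0.0 <= fit.rotation < math.pi

    def test_noisy_fit_close_to_orthogonal_refit(self, rng):
        """With Gaussian point noise the direct fit tracks a brute-force
        orthogonal-distance minimiser to well within the noise scale."""
        from scipy.optimize import least_squares

        truth = Ellipse(100.0, 80.0, 60.0, 40.0, 0.3)
        pts = ellipse_points(truth, 40, rng=rng, noise=0.5)
        fit = fit_ellipse(LandmarkSet("e1", "disc", pts))

        def resid(params):
            e = Ellipse(*params)
            return orthogonal_residuals(e, pts)

        refit = least_squares(
            resid, [100.0, 80.0, 60.0, 40.0, 0.3], method="lm"
        )
        oracle = Ellipse(*refit.x)
        assert fit.center_x == pytest.approx(oracle.center_x, abs=0.3)
        assert fit.center_y == pytest.approx(oracle.center_y, abs=0.3)
        assert fit.semi_major == pytest.approx(oracle.semi_major, abs=0.3)
        assert fit.semi_minor == pytest.approx(oracle.semi_minor, abs=0.3)

    def test_matches_skimage_direct_fit(self, rng):
        """Independent cross-check against scikit-image's ellipse model."""
        from skimage.measure import EllipseModel

        truth = Ellipse(250.0, 300.0, 90.0, 55.0, 1.1)
        pts = ellipse_points(truth, 30, rng=rng, noise=0.8)
        fit = fit_ellipse(LandmarkSet("e1", "disc", pts))
        em = EllipseModel.from_estimate(pts)
        assert em
        (xc, yc), (a, b) = em.center, em.axis_lengths
        if a < b:
            a, b = b, a
        assert fit.center_x == pytest.approx(xc, abs=1e-3)
        assert fit.center_y == pytest.approx(yc, abs=1e-3)
        assert fit.semi_major == pytest.approx(a, abs=1e-2)
        assert fit.semi_minor == pytest.approx(b, abs=1e-2)

    def test_error_cases(self):
        with pytest.raises(InsufficientLandmarksError):
            fit_ellipse(LandmarkSet("e1", "cup", np.zeros((4, 2))))
        line = np.column_stack([np.arange(8.0), 2.0 * np.arange(8.0)])
        with pytest.raises(NonEllipseError):
            fit_ellipse(LandmarkSet("e1", "cup", line))


class TestRayDistance:
    def test_circle_any_angle(self):
        circle = Ellipse(5.0, -3.0, 50.0, 50.0, 0.0)
        for angle in (0.0, 37.0, 123.4, 290.0):
            assert ray_boundary_distance(circle, (5.0, -3.0), angle) == pytest.approx(50.0)

    def test_axis_aligned_closed_form(self):
        e = Ellipse(0.0, 0.0, 40.0, 20.0, 0.0)
        # canonical 90 deg is horizontal (major axis); 180 deg vertical (minor)
        assert ray_boundary_distance(e, (0, 0), 90.0) == pytest.approx(40.0)
        assert ray_boundary_distance(e, (0, 0), 180.0) == pytest.approx(20.0)
        for psi in (30.0, 75.0, 140.0):
            rad = math.radians(psi)
            expected = 1.0 / math.sqrt((math.sin(rad) / 40.0) ** 2 + (math.cos(rad) / 20.0) ** 2)
            assert ray_boundary_distance(e, (0, 0), psi) == pytest.approx(expected)

    def test_offset_origin_matches_polygon_oracle(self, rng):
        e = Ellipse(3.0, -2.0, 60.0, 35.0, 0.7)
        origin = np.array([13.0, 3.0])
        for angle in rng.uniform(0.0, 360.0, 25):
            u = np.array([math.sin(math.radians(angle)), -math.cos(math.radians(angle))])
            mine = _ray_distance(e, origin, u)
            oracle = polygon_ray_distance(e, origin, u)
            assert mine == pytest.approx(oracle, abs=1e-3)

    def test_origin_outside_raises(self):
        e = Ellipse(0.0, 0.0, 40.0, 20.0, 0.0)
        with pytest.raises(GeometryError):
            ray_boundary_distance(e, (100.0, 0.0), 0.0)
        with pytest.raises(GeometryError):
            ray_boundary_distance(e, (40.0, 0.0), 0.0)  # on the boundary


class TestExtractProfile:
    def test_concentric_circles_constant(self):
        seg = DiscSegmentation("e", "right", Ellipse(0, 0, 30, 30, 0), Ellipse(0, 0, 60, 60, 0))
        assert np.allclose(extract_pcdr(seg).values, 0.5)

    def test_axis_aligned_cup_in_circular_disc(self):
        seg = DiscSegmentation("e", "right", Ellipse(0, 0, 40, 20, 0), Ellipse(0, 0, 50, 50, 0))
        v = extract_pcdr(seg).values
        assert v[5] == pytest.approx(0.8)   # d=6 -> 90 deg, horizontal major axis
        assert v[17] == pytest.approx(0.8)  # d=18 -> 270 deg
        assert v[11] == pytest.approx(0.4)  # d=12 -> 180 deg, vertical minor axis
        assert v[23] == pytest.approx(0.4)  # d=24 -> 360 deg

    def test_offset_cup_matches_polygon_oracle(self, rng):
        from pcdr.geometry import direction_vector, profile_angles_deg

        for _ in range(5):
            seg = random_valid_segmentation(rng)
            values = extract_pcdr(seg).values
            origin = seg.cup.center
            for j, angle in enumerate(profile_angles_deg()):
                if np.isnan(values[j]):
                    continue
                u = direction_vector(angle, seg.laterality)
                oracle = polygon_ray_distance(seg.cup, origin, u) / polygon_ray_distance(
                    seg.disc, origin, u
                )
                assert values[j] == pytest.approx(oracle, abs=1e-3)

    def test_cup_crossing_disc_gives_missing(self):
        # wide flat cup pokes out of a smaller circular disc horizontally
        with pytest.warns(UserWarning, match="missing"):
            profile = extract_pcdr(
                DiscSegmentation("e", "right", Ellipse(0, 0, 45, 10, 0), Ellipse(0, 0, 40, 40, 0))
            )
        assert np.isnan(profile.values[5])  # horizontal direction crossed
        assert not np.isnan(profile.values[11])  # vertical direction fine

    def test_scale_invariance(self):
        seg1 = DiscSegmentation(
            "e", "right", Ellipse(1, 2, 30, 25, 0.4), Ellipse(0, 0, 70, 60, 1.0)
        )
        seg2 = DiscSegmentation(
            "e", "right", Ellipse(3, 6, 90, 75, 0.4), Ellipse(0, 0, 210, 180, 1.0)
        )
        assert np.allclose(extract_pcdr(seg1).values, extract_pcdr(seg2).values)

    def test_rotation_equivariance(self, rng):
        """Rotating both ellipses and the sampling frame together leaves CDRs
        unchanged: a rotated configuration probed at shifted angles matches."""
        from pcdr.geometry import _ray_distance

        cup = Ellipse(5, -3, 30, 22, 0.5)
        disc = Ellipse(0, 0, 70, 55, 1.1)
        shift = math.radians(40.0)

        def rot(p, ang):
            c, s = math.cos(ang), math.sin(ang)
            return np.array([c * p[0] - s * p[1], s * p[0] + c * p[1]])

        cup_r = Ellipse(*rot((5, -3), shift), 30, 22, (0.5 + shift) % math.pi)
        disc_r = Ellipse(*rot((0, 0), shift), 70, 55, (1.1 + shift) % math.pi)
        for angle in rng.uniform(0, 2 * math.pi, 10):
            u = np.array([math.cos(angle), math.sin(angle)])
            ratio = _ray_distance(cup, cup.center, u) / _ray_distance(disc, cup.center, u)
            u_r = rot(u, shift)
            ratio_r = _ray_distance(cup_r, cup_r.center, u_r) / _ray_distance(
                disc_r, cup_r.center, u_r
            )
            assert ratio == pytest.approx(ratio_r, rel=1e-9)

    def test_mirror_left_right_equivalence(self):
        """A left eye that is the exact mirror image of a right eye yields an
        identical canonical profile."""
        cup_r = Ellipse(5, 3, 30, 25, 0.4)
        disc_r = Ellipse(2, 1, 70, 60, 1.0)
        cup_l = Ellipse(-5, 3, 30, 25, (math.pi - 0.4) % math.pi)
        disc_l = Ellipse(-2, 1, 70, 60, (math.pi - 1.0) % math.pi)
        right = extract_pcdr(DiscSegmentation("r", "right", cup_r, disc_r))
        left = extract_pcdr(DiscSegmentation("l", "left", cup_l, disc_l))
        assert np.allclose(right.values, left.values)

    def test_values_in_unit_interval(self, rng):
        for _ in range(20):
            seg = random_valid_segmentation(rng)
            v = extract_pcdr(seg).values
            obs = v[~np.isnan(v)]
            assert np.all((obs > 0) & (obs < 1))


class TestCanonicalOrientation:
    def test_right_eye_identity(self):
        v = np.arange(24.0)
        assert np.array_equal(canonical_orientation(v, "right"), v)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_left_eye_involution(self, seed):
        v = np.random.default_rng(seed).uniform(0.1, 0.9, 24)
        twice = canonical_orientation(canonical_orientation(v, "left"), "left")
        assert np.allclose(twice, v)

    def test_mirror_pairs(self):
        v = np.arange(1.0, 25.0)
        out = canonical_orientation(v, "left")
        # d <-> 24 - d: canonical slot 1 holds raw direction 23, etc.
        assert out[0] == 23.0 and out[22] == 1.0
        assert out[11] == 12.0 and out[23] == 24.0  # fixed points on the vertical

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            canonical_orientation(np.ones(23), "left")


class TestDDLSScalars:
    def test_rtd_basics(self):
        p = CDRProfile("e", "right", "healthy", np.full(24, 0.5))
        assert rim_to_disc_narrowest(p) == pytest.approx(0.5)
        v = np.full(24, 0.5)
        v[7] = 0.9
        assert rim_to_disc_narrowest(CDRProfile("e", "right", "healthy", v)) == pytest.approx(0.1)

    def test_rtd_with_missing_matches_exhaustive_scan(self, rng):
        v = rng.uniform(0.2, 0.8, 24)
        v[rng.choice(24, size=6, replace=False)] = np.nan
        p = CDRProfile("e", "left", "glaucoma", v)
        expected = min(1.0 - x for x in v if not np.isnan(x))
        assert rim_to_disc_narrowest(p) == pytest.approx(expected)

    def test_all_missing_profile_rejected_at_construction(self):
        with pytest.raises(EmptyProfileError):
            CDRProfile("e", "right", "healthy", np.full(24, np.nan))

    def test_dsv(self):
        assert vertical_disc_size(Ellipse(0, 0, 50, 50, 0)) == pytest.approx(100.0)
        assert vertical_disc_size(Ellipse(10, -4, 60, 40, 0)) == pytest.approx(80.0)

    def test_dsv_rotated_matches_polygon_chord(self):
        e = Ellipse(210.0, 305.0, 80.0, 45.0, 0.9)
        assert vertical_disc_size(e) == pytest.approx(
            polygon_vertical_chord(e, e.center_x), abs=1e-3
        )

    def test_vcdr_closed_forms(self):
        seg = DiscSegmentation("e", "right", Ellipse(0, 0, 30, 30, 0), Ellipse(0, 0, 60, 60, 0))
        assert vertical_cdr(seg) == pytest.approx(0.5)
        seg2 = DiscSegmentation("e", "right", Ellipse(0, 0, 40, 20, 0), Ellipse(0, 0, 50, 50, 0))
        assert vertical_cdr(seg2) == pytest.approx(0.4)

    def test_vcdr_offset_matches_polygon_oracle(self, rng):
        for _ in range(5):
            seg = random_valid_segmentation(rng)
            cup_chord = polygon_vertical_chord(seg.cup, seg.cup.center_x)
            disc_chord = polygon_vertical_chord(seg.disc, seg.cup.center_x)
            v = vertical_cdr(seg)
            if np.isnan(v):
                continue
            assert v == pytest.approx(cup_chord / disc_chord, abs=1e-3)


class TestTypeInvariants:
    def test_ellipse_axis_order_enforced(self):
        with pytest.raises(GeometryError):
            Ellipse(0, 0, 20, 40, 0)
        assert Ellipse(0, 0, 40, 20, math.pi + 0.3).rotation == pytest.approx(0.3)

    def test_cup_centre_must_be_inside_disc(self):
        with pytest.raises(GeometryError):
            DiscSegmentation("e", "right", Ellipse(200, 0, 30, 20, 0), Ellipse(0, 0, 60, 50, 0))

    def test_profile_value_range_enforced(self):
        v = np.full(24, 0.5)
        v[3] = 1.2
        with pytest.raises(ValueError):
            CDRProfile("e", "right", "healthy", v)
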