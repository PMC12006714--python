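"""Coronal/transverse frame construction and medial-wall quadrant mapping."""

import numpy as np
import pytest

from femquad.errors import (AmbiguousOrientationError, DegenerateGeometryError,
                            DegenerateInputError)
from femquad.frame import (build_frame, classify_quadrant, extract_lowest_point,
                           signed_coordinates)
from femquad.primitives import CylinderFit, SphereFit
from .conftest import random_rigid


def _sphere(center, radius=10.0):
    return SphereFit(center=np.asarray(center, float), radius=radius,
                     rms_residual=0.0, n_points=100, coverage_fraction=1.0)


def _cylinder(c1, c2, radius=14.0):
    return CylinderFit(c1=np.asarray(c1, float), c2=np.asarray(c2, float),
                       radius=radius, rms_residual=0.0, n_points=100)


@pytest.fixture()
def canonical_frame():
    # shaft along +z, head at (0, 30, 80), LT at (2, 12, 20), anterior +x
    return build_frame(_sphere([0, 30, 80], 24.0), _sphere([2, 12, 20]),
                       _cylinder([0, 0, 0], [0, 0, 50]), anterior_ref=[10, 0, 0])


class TestBuildFrame:
    def test_canonical_axis_aligned_planes(self, canonical_frame):
        f = canonical_frame
        assert np.allclose(f.Pc.unit_normal, [1, 0, 0], atol=1e-12)
        assert f.Pc.signed_distance([0, 7, -3]) == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(f.Pa.unit_normal, [0, 0, 1], atol=1e-12)
        assert f.Pa.signed_distance([5, -2, 20]) == pytest.approx(0.0, abs=1e-12)

    def test_c2_is_proximal_endpoint(self, canonical_frame):
        # endpoints supplied distal-first or proximal-first give the same frame
        f2 = build_frame(_sphere([0, 30, 80], 24.0), _sphere([2, 12, 20]),
                         _cylinder([0, 0, 50], [0, 0, 0]), anterior_ref=[10, 0, 0])
        assert np.allclose(f2.C2, canonical_frame.C2)
        assert np.allclose(f2.C2, [0, 0, 50])
        assert (f2.C2 - f2.C1) @ f2.Pa.unit_normal > 0

    def test_frame_invariants(self, canonical_frame):
        f = canonical_frame
        for p in (f.O, f.C1, f.C2):
            assert abs(f.Pc.signed_distance(p)) < 1e-6
        assert abs(f.Pa.signed_distance(f.O1)) < 1e-6
        assert abs(f.Pc.unit_normal @ f.Pa.unit_normal) < 1e-9

    def test_collinear_head_and_axis_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            build_frame(_sphere([0, 0, 100]), _sphere([2, 12, 20]),
                        _cylinder([0, 0, 0], [0, 0, 50]), anterior_ref=[10, 0, 0])

    def test_anterior_ref_on_plane_rejected(self):
        with pytest.raises(AmbiguousOrientationError):
            build_frame(_sphere([0, 30, 80]), _sphere([2, 12, 20]),
                        _cylinder([0, 0, 0], [0, 0, 50]), anterior_ref=[0.05, 15, 0])

    def test_posterior_reference_flips_normal(self, canonical_frame):
        f2 = build_frame(_sphere([0, 30, 80], 24.0), _sphere([2, 12, 20]),
                         _cylinder([0, 0, 0], [0, 0, 50]), anterior_ref=[-10, 0, 0])
        assert np.allclose(f2.Pc.unit_normal, -canonical_frame.Pc.unit_normal)


class TestSignedCoordinates:
    def test_canonical_arithmetic(self, canonical_frame):
        c = signed_coordinates(canonical_frame, [5, 15, 26])
        assert c.X == pytest.approx(5.0, abs=1e-12)
        assert c.Y == pytest.approx(6.0, abs=1e-12)
        assert c.quadrant == "Q1"

    def test_origin_of_both_planes_is_q1(self, canonical_frame):
        c = signed_coordinates(canonical_frame, [0, 9, 20])  # X = 0, Y = 0
        assert (c.X, c.Y) == (0.0, 0.0)
        assert c.quadrant == "Q1"

    def test_rigid_motion_invariance(self, rng):
        D = np.array([5.0, 15.0, 26.0])
        for trial in range(10):
            Q, t = random_rigid(np.random.default_rng(900 + trial))
            f = build_frame(
                _sphere(Q @ [0, 30, 80] + t, 24.0), _sphere(Q @ [2, 12, 20] + t),
                _cylinder(Q @ [0, 0, 0.0] + t, Q @ [0, 0, 50.0] + t),
                anterior_ref=Q @ [10, 0, 0.0] + t)
            c = signed_coordinates(f, Q @ D + t)
            assert c.X == pytest.approx(5.0, abs=1e-6)
            assert c.Y == pytest.approx(6.0, abs=1e-6)
            assert c.quadrant == "Q1"

    def test_mirror_consistency(self, canonical_frame):
        """Mirroring a right case across the sagittal-ish plane x=0 and flagging
        it left leaves (X, Y) unchanged: the anterior reference re-orients the
        coronal normal."""
        M = np.diag([-1.0, 1.0, 1.0])
        f = build_frame(_sphere(M @ [0, 30, 80], 24.0), _sphere(M @ [2, 12, 20]),
                        _cylinder(M @ [0, 0, 0.0], M @ [0, 0, 50.0]),
                        anterior_ref=M @ [10, 0, 0.0], side="left")
        c_right = signed_coordinates(canonical_frame, [5, 15, 26])
        c_left = signed_coordinates(f, M @ [5, 15, 26])
        assert c_left.X == pytest.approx(c_right.X, abs=1e-12)
        assert c_left.Y == pytest.approx(c_right.Y, abs=1e-12)
        assert c_left.quadrant == c_right.quadrant


class TestClassifyQuadrant:
    @pytest.mark.parametrize("X,Y,expected", [
        (6.44, 6.14, "Q1"),     # reference-series Q1 mean pair
        (-7.23, 8.31, "Q2"),    # Q2 mean pair
        (-9.59, -24.43, "Q3"),  # Q3 mean pair
        (8.18, -18.20, "Q4"),   # Q4 mean pair
        (0.0, -5.0, "Q4"),      # X = 0 counts as positive
        (0.0, 0.0, "Q1"),
        (-1e-12, 0.0, "Q2"),
    ])
    def test_sign_pattern(self, X, Y, expected):
        assert classify_quadrant(X, Y) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(DegenerateInputError):
            classify_quadrant(float("nan"), 0.0)


class TestLowestPoint:
    def test_argmin_in_y(self, canonical_frame):
        pts = [[0, 10, 24], [0, 10, 14], [0, 10, 27]]  # Y = 4, -2, 7
        assert np.allclose(extract_lowest_point(pts, canonical_frame), [0, 10, 14])

    def test_tie_broken_by_minimal_x(self, canonical_frame):
        pts = [[3, 10, 14], [-1, 10, 14]]
        assert np.allclose(extract_lowest_point(pts, canonical_frame), [-1, 10, 14])

    def test_full_tie_broken_lexicographically(self, canonical_frame):
        pts = [[2, 11, 14], [2, 10, 14]]  # same X and Y, differ in the free direction
        assert np.allclose(extract_lowest_point(pts, canonical_frame), [2, 10, 14])

    def test_empty_line_rejected(self, canonical_frame):
        with pytest.raises(DegenerateInputError):
            extract_lowest_point([], canonical_frame)
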