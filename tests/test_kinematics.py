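"""Geometric core: angles vs. the arccos oracle, CoM, body frame, floor."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from motionkit.errors import (
    DegenerateGeometryError,
    MissingJointError,
    NoFloorFoundError,
)
from motionkit.kinematics import (
    COM_SEGMENTS,
    BodyFrame,
    SegmentWeights,
    build_body_frame,
    com_trajectory,
    compute_com,
    fit_floor_plane,
    head_bend_angles,
    segment_angle,
    trunk_angle,
    angular_velocity,
)
from motionkit.skeleton import AngleSignal, SkeletonSequence

from conftest import make_signal


def arccos_oracle(u, v):
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    return np.degrees(np.arccos(np.clip(u @ v, -1, 1)))


finite_coord = st.floats(-5, 5, allow_nan=False)
point = st.tuples(finite_coord, finite_coord, finite_coord).map(np.array)


class TestAngles:
    def test_collinear_is_180(self):
        assert segment_angle([0, 1, 0], [0, 0, 0], [0, -1, 0]) == pytest.approx(180.0)

    def test_orthogonal_is_90(self):
        assert segment_angle([1, 0, 0], [0, 0, 0], [0, 1, 0]) == pytest.approx(90.0)

    def test_random_triples_match_arccos_oracle(self, rng):
        for _ in range(1000):
            a, b, c = rng.uniform(-2, 2, (3, 3))
            if np.allclose(a, b) or np.allclose(c, b):
                continue
            expected = arccos_oracle(a - b, c - b)
            assert segment_angle(a, b, c) == pytest.approx(expected, abs=1e-9)

    def test_vectorized_matches_scalar(self, rng):
        a, b, c = rng.uniform(-1, 1, (3, 50, 3))
        vec = segment_angle(a, b, c)
        for i in range(50):
            assert vec[i] == pytest.approx(segment_angle(a[i], b[i], c[i]), abs=1e-12)

    def test_zero_length_segment_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            segment_angle([0, 0, 0], [0, 0, 0], [1, 0, 0])

    def test_trunk_angle_parallel_and_orthogonal(self):
        assert trunk_angle([0, 0, 1], [0, 0, 0], [0, 0, 1]) == pytest.approx(0.0)
        assert trunk_angle([1, 0, 0], [0, 0, 0], [0, 0, 1]) == pytest.approx(90.0)

    def test_trunk_angle_matches_oracle(self, rng):
        for _ in range(200):
            s, b = rng.uniform(-1, 1, (2, 3))
            v = rng.uniform(-1, 1, 3)
            if np.allclose(s, b) or np.linalg.norm(v) < 1e-3:
                continue
            assert trunk_angle(s, b, v) == pytest.approx(
                arccos_oracle(s - b, v), abs=1e-9
            )


class TestBodyFrame:
    def upright(self):
        return {
            "ShouldL": np.array([-0.2, 0.0, 1.4]),
            "ShouldR": np.array([0.2, 0.0, 1.4]),
            "SpineB": np.array([0.0, 0.0, 1.0]),
            "SpineS": np.array([0.0, 0.0, 1.4]),
        }

    def test_axis_aligned_construction(self):
        f = build_body_frame(self.upright())
        assert abs(abs(f.ml @ [1, 0, 0]) - 1) < 1e-9
        assert abs(abs(f.ap @ [0, 1, 0]) - 1) < 1e-9
        assert abs(f.vertical @ [0, 0, 1] - 1) < 1e-9

    def test_rotation_about_vertical_rotates_axes(self):
        ang = np.radians(30)
        R = np.array(
            [[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]]
        )
        base = self.upright()
        f0 = build_body_frame(base)
        f1 = build_body_frame({k: R @ v for k, v in base.items()})
        np.testing.assert_allclose(f1.ml, R @ f0.ml, atol=1e-9)
        np.testing.assert_allclose(f1.ap, R @ f0.ap, atol=1e-9)

    def test_nonorthogonal_input_yields_orthogonal_frame(self):
        j = self.upright()
        j["ShouldL"] = np.array([-0.2, 0.05, 1.5])  # tilted shoulder line
        f = build_body_frame(j)
        assert abs(f.ap @ f.ml) < 1e-6
        assert abs(f.ap @ f.vertical) < 1e-6
        assert np.cross(f.ap, f.ml) @ f.vertical > 0  # right-handed

    def test_coincident_shoulders_rejected(self):
        j = self.upright()
        j["ShouldL"] = j["ShouldR"]
        with pytest.raises(DegenerateGeometryError):
            build_body_frame(j)


class TestHeadBend:
    def frame(self):
        return BodyFrame(
            ap=np.array([0.0, 1.0, 0.0]),
            ml=np.array([-1.0, 0.0, 0.0]),
            vertical=np.array([0.0, 0.0, 1.0]),
        )

    def test_aligned_head_gives_zero(self):
        fwd, lat = head_bend_angles(
            [0, 0, 1.7], [0, 0, 1.4], [0, 0, 1.0], self.frame()
        )
        assert fwd == pytest.approx(0.0, abs=1e-9)
        assert lat == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("deg", [10.0, -10.0, 3.5])
    def test_pure_sagittal_tilt(self, deg):
        r = np.radians(deg)
        head = np.array([0, 0, 1.4]) + 0.3 * np.array([0, np.sin(r), np.cos(r)])
        fwd, lat = head_bend_angles(head, [0, 0, 1.4], [0, 0, 1.0], self.frame())
        assert fwd == pytest.approx(deg, abs=1e-6)
        assert lat == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("deg", [7.0, -7.0])
    def test_pure_lateral_tilt(self, deg):
        r = np.radians(deg)
        # subject-left is -x in this frame
        head = np.array([0, 0, 1.4]) + 0.3 * np.array([-np.sin(r), 0, np.cos(r)])
        fwd, lat = head_bend_angles(head, [0, 0, 1.4], [0, 0, 1.0], self.frame())
        assert lat == pytest.approx(deg, abs=1e-6)
        assert fwd == pytest.approx(0.0, abs=1e-6)

    def test_head_coincident_with_spine_s_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            head_bend_angles([0, 0, 1.4], [0, 0, 1.4], [0, 0, 1.0], self.frame())


class TestCom:
    def joints(self, rng):
        names = sorted({j for _, p, d in COM_SEGMENTS for j in (p, d)})
        return {n: rng.uniform(-1, 1, 3) for n in names}

    def test_two_segment_symmetry(self):
        # equal-weight symmetric segments: CoM at the midpoint
        j = {
            "Head": [1, 0, 0], "SpineS": [1, 0, 0],
            "ShouldR": [-1, 0, 0], "WristR": [-1, 0, 0],
            "ShouldL": [1, 0, 0], "WristL": [1, 0, 0],
            "SpineS": [1, 0, 0], "SpineB": [1, 0, 0],
            "HipR": [-1, 0, 0], "AnkleR": [-1, 0, 0],
            "HipL": [-1, 0, 0], "AnkleL": [-1, 0, 0],
        }
        w = SegmentWeights(
            {"head_trunk_upper": 1, "arm_right": 1, "arm_left": 1,
             "trunk": 1, "leg_right": 1, "leg_left": 1}
        )
        np.testing.assert_allclose(compute_com(j, w), [0, 0, 0], atol=1e-12)

    def test_constant_centroids_give_that_point(self, rng):
        p = rng.uniform(-1, 1, 3)
        j = {n: p for n in
             {x for _, a, b in COM_SEGMENTS for x in (a, b)}}
        np.testing.assert_allclose(compute_com(j), p, atol=1e-12)

    def test_matches_weighted_sum_oracle(self, rng):
        for _ in range(50):
            j = self.joints(rng)
            w = SegmentWeights()
            wn = np.array([w.weights[n] for n, _, _ in COM_SEGMENTS])
            wn = wn / wn.sum()
            oracle = sum(
                wi * 0.5 * (np.asarray(j[p]) + np.asarray(j[d]))
                for wi, (_, p, d) in zip(wn, COM_SEGMENTS)
            )
            np.testing.assert_allclose(compute_com(j), oracle, atol=1e-12)

    def test_unnormalized_mode_divides_by_n(self, rng):
        j = self.joints(rng)
        w = SegmentWeights(normalize=False)
        raw = np.array([w.weights[n] for n, _, _ in COM_SEGMENTS])
        oracle = sum(
            wi / 6.0 * 0.5 * (np.asarray(j[p]) + np.asarray(j[d]))
            for wi, (_, p, d) in zip(raw, COM_SEGMENTS)
        )
        np.testing.assert_allclose(compute_com(j, w), oracle, atol=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(shift=point, seed=st.integers(0, 100))
    def test_affine_equivariance(self, shift, seed):
        rng = np.random.default_rng(seed)
        j = self.joints(rng)
        ang = 0.7
        R = np.array(
            [[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]]
        )
        moved = {k: R @ np.asarray(v) + shift for k, v in j.items()}
        np.testing.assert_allclose(
            compute_com(moved), R @ compute_com(j) + shift, atol=1e-9
        )

    def test_missing_joint_named(self, rng):
        j = self.joints(rng)
        del j["WristL"]
        with pytest.raises(MissingJointError, match="WristL"):
            compute_com(j)


class TestComTrajectory:
    def sequence(self, offsets):
        """Static skeleton translated by per-frame offsets (T, 3)."""
        base = {
            "Head": [0, 0, 1.7], "SpineS": [0, 0, 1.4], "SpineB": [0, 0, 1.0],
            "ShouldL": [-0.2, 0, 1.4], "ShouldR": [0.2, 0, 1.4],
            "WristL": [-0.25, 0, 0.9], "WristR": [0.25, 0, 0.9],
            "HipL": [-0.1, 0, 1.0], "HipR": [0.1, 0, 1.0],
            "AnkleL": [-0.1, 0, 0.1], "AnkleR": [0.1, 0, 0.1],
        }
        offsets = np.asarray(offsets, float)
        n = offsets.shape[0]
        joints = {k: np.asarray(v, float) + offsets for k, v in base.items()}
        return SkeletonSequence(t=np.arange(n) / 30.0, joints=joints)

    def frame(self):
        return BodyFrame(
            ap=np.array([0.0, 1.0, 0.0]),
            ml=np.array([-1.0, 0.0, 0.0]),
            vertical=np.array([0.0, 0.0, 1.0]),
        )

    def test_static_skeleton_zero_sway(self):
        com = com_trajectory(self.sequence(np.zeros((30, 3))), self.frame())
        np.testing.assert_allclose(com.ap, 0, atol=1e-12)
        np.testing.assert_allclose(com.ml, 0, atol=1e-12)

    def test_pure_ap_oscillation_stays_out_of_ml(self):
        t = np.arange(60) / 30.0
        offs = np.column_stack([np.zeros(60), 0.01 * np.sin(2 * np.pi * t), np.zeros(60)])
        com = com_trajectory(self.sequence(offs), self.frame())
        np.testing.assert_allclose(com.ml, 0, atol=1e-9)
        # 1 cm amplitude -> 2 cm range (up to the 30 Hz sampling of the peak)
        assert np.ptp(com.ap) == pytest.approx(2.0, rel=0.02)


class TestFloorPlane:
    def test_noiseless_plane_exact(self, rng):
        pts = np.column_stack(
            [rng.uniform(-2, 2, 200), rng.uniform(-2, 2, 200), np.zeros(200)]
        )
        fp = fit_floor_plane(pts, (0, 0, 1), seed=0)
        np.testing.assert_allclose(fp.normal, [0, 0, 1], atol=1e-9)
        assert fp.offset == pytest.approx(0.0, abs=1e-9)

    def test_outlier_robust_recovery_statistical(self):
        ok = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            plane = np.column_stack(
                [rng.uniform(-2, 2, 400), rng.uniform(-2, 2, 400),
                 rng.normal(0, 0.002, 400)]
            )
            outliers = rng.uniform(-2, 2, (100, 3))
            outliers[:, 2] = rng.uniform(0.2, 2, 100)
            fp = fit_floor_plane(np.vstack([plane, outliers]), (0, 0, 1), seed=seed)
            ang = np.degrees(np.arccos(np.clip(fp.normal[2], -1, 1)))
            ok += ang < 1.0
        assert ok >= 99

    def test_collinear_cloud_rejected(self, rng):
        line = np.outer(np.linspace(0, 1, 60), [1.0, 2.0, 0.5])
        with pytest.raises(NoFloorFoundError):
            fit_floor_plane(line, (0, 0, 1), seed=0)

    def test_feet_prior_rejects_distant_plane(self, rng):
        pts = np.column_stack(
            [rng.uniform(-2, 2, 200), rng.uniform(-2, 2, 200), np.zeros(200)]
        )
        feet = np.array([[0.0, 0.0, 0.5]])  # half a meter off the plane
        with pytest.raises(NoFloorFoundError):
            fit_floor_plane(pts, (0, 0, 1), feet=feet, seed=0)


class TestAngularVelocity:
    def test_linear_ramp(self):
        t = np.arange(0, 3, 0.01)
        sig = AngleSignal("r", t, 5.0 * t, 100.0)
        np.testing.assert_allclose(angular_velocity(sig), 5.0, atol=1e-6)

    def test_sinusoid_peak_velocity(self):
        sig = make_signal(10 * np.sin(2 * np.pi * 1.0 * np.arange(0, 5, 0.01)))
        v = angular_velocity(sig)
        assert np.max(np.abs(v)) == pytest.approx(2 * np.pi * 10, rel=0.005)

    def test_constant_signal_zero(self):
        sig = make_signal(np.full(200, 42.0))
        np.testing.assert_allclose(angular_velocity(sig), 0.0, atol=1e-9)
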