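"""Cycle segmentation, per-task feature vectors, sway geometry."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from motionkit.errors import (
    IncompleteSitToStandError,
    InsufficientMovementError,
    MissingJointError,
)
from motionkit.features import (
    ExtractionConfig,
    MovementCycle,
    ac_features,
    extract_task,
    la_features,
    po_features,
    segment_cycles,
    sway_features,
)
from motionkit.kinematics import ComTrajectory
from motionkit.skeleton import AngleSignal
from motionkit.synthetic import DEFAULT_PROFILES, TrialRecipe, gen_la_trial

from conftest import make_signal, raised_cosine_train


def cyc(amplitude, duration, peak_speed=100.0, start=0):
    n = max(int(duration * 100), 2)
    return MovementCycle(
        i_min1=start, i_max=start + n // 2, i_min2=start + n,
        amplitude=amplitude, duration=duration, peak_speed=peak_speed,
    )


def hull_area_bruteforce(points):
    """O(n^3) extreme-point hull + shoelace, independent of scipy.

    A point is an extreme (hull) point iff it lies strictly inside no
    triangle formed by three other points.
    """
    pts = np.unique(np.asarray(points, float), axis=0)
    if len(pts) < 3:
        return 0.0
    n = len(pts)
    tri = np.array(list(itertools.combinations(range(n), 3)))
    a, b, c = pts[tri[:, 0]], pts[tri[:, 1]], pts[tri[:, 2]]

    def cross2(u, v):
        return u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]

    hull = []
    for i, p in enumerate(pts):
        others = ~np.any(tri == i, axis=1)
        d1 = cross2(b[others] - a[others], p - a[others])
        d2 = cross2(c[others] - b[others], p - b[others])
        d3 = cross2(a[others] - c[others], p - c[others])
        inside = ((d1 > 1e-12) & (d2 > 1e-12) & (d3 > 1e-12)) | (
            (d1 < -1e-12) & (d2 < -1e-12) & (d3 < -1e-12)
        )
        if not inside.any():
            hull.append(p)
    hull = np.asarray(hull)
    center = hull.mean(axis=0)
    order = np.argsort(np.arctan2(hull[:, 1] - center[1], hull[:, 0] - center[0]))
    hull = hull[order]
    x, y = hull[:, 0], hull[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


class TestSegmentCycles:
    def test_constant_signal_no_cycles(self):
        assert segment_cycles(make_signal(np.full(300, 5.0))) == []

    def test_five_period_sinusoid(self):
        T = 1.0
        t = np.arange(0, 5 * T + 0.01, 0.01)
        sig = AngleSignal("s", t, 10 - 10 * np.cos(2 * np.pi * t / T), 100.0)
        cycles = segment_cycles(sig)
        assert len(cycles) == 5
        for c in cycles:
            assert c.duration == pytest.approx(T, abs=0.0101)
            assert c.amplitude == pytest.approx(20.0, abs=0.01)

    def test_single_triangular_pulse(self):
        t = np.arange(0, 1.0 + 0.005, 0.01)
        v = 30 * (1 - np.abs(t - 0.5) / 0.5)
        cycles = segment_cycles(AngleSignal("tri", t, v, 100.0))
        assert len(cycles) == 1
        assert cycles[0].amplitude == pytest.approx(30.0, abs=0.5)
        assert cycles[0].duration == pytest.approx(1.0, abs=0.02)

    def test_cycles_ordered_nonoverlapping_shared_boundaries(self):
        sig = raised_cosine_train([0.5] * 6, [20, 25, 18, 22, 30, 24])
        cycles = segment_cycles(sig)
        assert len(cycles) == 6
        for a, b in zip(cycles, cycles[1:]):
            assert a.i_min2 <= b.i_min1  # ordered, non-overlapping
        # interior boundaries shared between adjacent cycles
        assert all(a.i_min2 == b.i_min1 for a, b in zip(cycles[1:-2], cycles[2:-1]))

    def test_trailing_rise_without_closing_descent_not_a_cycle(self):
        t = np.arange(0, 2, 0.01)
        v = np.where(t < 1, 10 - 10 * np.cos(2 * np.pi * t), 20 * (t - 1))
        cycles = segment_cycles(AngleSignal("x", t, v, 100.0))
        # only the complete first bump forms a cycle
        assert len(cycles) == 1

    def test_prominence_threshold_suppresses_small_wiggles(self):
        t = np.arange(0, 4, 0.01)
        v = 0.3 * np.sin(2 * np.pi * 2 * t)  # 0.6 deg peak-to-peak
        assert segment_cycles(AngleSignal("w", t, v, 100.0), min_prominence=1.0) == []


class TestLaFeatures:
    def test_identical_cycles_zero_dispersion(self):
        f = la_features([cyc(30, 0.5, 120) for _ in range(10)])
        assert f.MKAm == pytest.approx(30.0)
        assert f.MKAv == 0.0
        assert f.TDm == pytest.approx(0.5)
        assert f.TDv == 0.0
        assert f.SPm == pytest.approx(120.0)
        assert f.PM == 0

    def test_worked_example_poor_movement_rule(self):
        # 9 x (30 deg, 0.5 s) + 1 x (5 deg, 0.1 s):
        # MKAm = 27.5, TDm = 0.46; 5 < 6.875 and 0.1 < 0.115 -> PM = 1
        cycles = [cyc(30, 0.5) for _ in range(9)] + [cyc(5, 0.1)]
        f = la_features(cycles)
        assert f.MKAm == pytest.approx(27.5)
        assert f.TDm == pytest.approx(0.46)
        assert f.PM == 1

    def test_poor_cycles_can_be_excluded_from_means(self):
        cycles = [cyc(30, 0.5) for _ in range(9)] + [cyc(5, 0.1)]
        f = la_features(cycles, include_poor_in_means=False)
        assert f.MKAm == pytest.approx(30.0)
        assert f.TDm == pytest.approx(0.5)
        assert f.PM == 1

    def test_sample_mean_recovery(self):
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            amps = rng.normal(25, 3, 12)
            f = la_features([cyc(a, 0.5) for a in amps])
            hits += abs(f.MKAm - 25) < 3 * 3 / np.sqrt(12)
        assert hits >= 190  # ~3 SE band

    def test_empty_cycle_list_rejected(self):
        with pytest.raises(InsufficientMovementError):
            la_features([])


class TestAcFeatures:
    def test_single_smooth_bend(self):
        sig = raised_cosine_train([2.0], [30.0])
        f = ac_features(sig)
        assert f.MBA == pytest.approx(30.0, abs=0.2)
        assert f.TD == pytest.approx(2.0, abs=0.04)
        assert f.NPeaks == 1

    def test_secondary_instability_peak_counted(self):
        sig = raised_cosine_train([2.0, 0.8], [30.0, 6.0])
        f = ac_features(sig)
        assert f.NPeaks == 2
        assert f.MBA == pytest.approx(30.0, abs=0.2)
        assert f.TD == pytest.approx(2.0, abs=0.05)

    def test_mean_speed_within_main_cycle(self):
        sig = raised_cosine_train([2.0], [30.0])
        f = ac_features(sig)
        # raised cosine: mean |d theta/dt| over the cycle = 2A/TD
        assert f.SPm == pytest.approx(2 * 30.0 / 2.0, rel=0.05)

    def test_flat_signal_incomplete_sit_to_stand(self):
        with pytest.raises(IncompleteSitToStandError):
            ac_features(make_signal(np.full(400, 2.0)))


class TestPoFeatures:
    def phase(self, trunk, fwd, lat, n=600):
        return {
            "ANG_TRUNK": make_signal(np.full(n, trunk), name="ANG_TRUNK"),
            "ANG_FORHEAD": make_signal(np.full(n, fwd), name="ANG_FORHEAD"),
            "ANG_LATHEAD": make_signal(np.full(n, lat), name="ANG_LATHEAD"),
        }

    def test_identical_phases_zero_deltas(self):
        p = self.phase(-4.0, -2.0, 1.5)
        f = po_features(p, self.phase(-4.0, -2.0, 1.5))
        assert f.FTB_d == f.FHB_d == f.LHB_d == 0.0

    def test_hand_computed_variation(self):
        f = po_features(self.phase(-6.0, -2.0, 1.0), self.phase(-5.0, -2.5, 1.4))
        assert f.FTB == pytest.approx(-6.0)
        assert f.FTB_d == pytest.approx(1.0)
        assert f.FHB_d == pytest.approx(0.5)

    def test_lateral_bend_reported_absolute(self):
        f = po_features(self.phase(0.0, 0.0, -3.0), self.phase(0.0, 0.0, -3.0))
        assert f.LHB == pytest.approx(3.0)

    def test_short_phase_rejected(self):
        from motionkit.errors import InsufficientDataError

        with pytest.raises(InsufficientDataError):
            po_features(self.phase(0, 0, 0, n=100), self.phase(0, 0, 0))


class TestSwayFeatures:
    def com(self, ap, ml, duration):
        ap = np.asarray(ap, float)
        t = np.linspace(0, duration, ap.size)
        return ComTrajectory(t=t, com3d=np.empty((ap.size, 0)), ap=ap, ml=np.asarray(ml, float))

    def test_stationary_com_all_zero(self):
        f = sway_features(self.com(np.zeros(50), np.zeros(50), 5.0))
        assert (f.APr, f.MLr, f.APt, f.MLt, f.APv, f.MLv, f.SwayArea) == (0,) * 7

    def test_unit_square_path(self):
        ap = [0, 1, 1, 0, 0]
        ml = [0, 0, 1, 1, 0]
        f = sway_features(self.com(ap, ml, 4.0))
        assert f.APr == 1 and f.MLr == 1
        assert f.APt == 2 and f.MLt == 2
        assert f.APv == pytest.approx(0.5) and f.MLv == pytest.approx(0.5)
        assert f.SwayArea == pytest.approx(1.0)

    def test_hull_area_matches_bruteforce_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 30))
            ap, ml = rng.normal(size=(2, n))
            f = sway_features(self.com(ap, ml, 10.0))
            assert f.SwayArea == pytest.approx(
                hull_area_bruteforce(np.column_stack([ap, ml])), abs=1e-9
            )

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(angle=st.floats(0, 2 * np.pi), scale=st.floats(0.1, 10), seed=st.integers(0, 50))
    def test_area_rotation_invariant_and_scales_quadratically(self, angle, scale, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(40, 2))
        base = sway_features(self.com(pts[:, 0], pts[:, 1], 1.0)).SwayArea
        R = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        rot = pts @ R.T * scale
        got = sway_features(self.com(rot[:, 0], rot[:, 1], 1.0)).SwayArea
        assert got == pytest.approx(base * scale**2, rel=1e-9)

    def test_path_length_monotone_in_appended_samples(self, rng):
        ap = rng.normal(size=100)
        ml = rng.normal(size=100)
        paths = [
            sway_features(self.com(ap[:n], ml[:n], n / 10)).APt for n in range(2, 101)
        ]
        assert np.all(np.diff(paths) >= -1e-12)

    def test_collinear_path_zero_area(self):
        ap = np.linspace(0, 1, 30)
        f = sway_features(self.com(ap, 2 * ap, 3.0))
        assert f.SwayArea == 0.0


class TestExtractTask:
    def test_missing_joint_error_names_joint(self):
        seq, _ = gen_la_trial(TrialRecipe("la_right", DEFAULT_PROFILES["HC"], seed=0))
        del seq.joints["SpineS"]
        with pytest.raises(MissingJointError, match="SpineS"):
            extract_task(seq, "ac")

    def test_unknown_task_rejected(self):
        seq, _ = gen_la_trial(TrialRecipe("la_right", DEFAULT_PROFILES["HC"], seed=0))
        with pytest.raises(ValueError, match="unknown task"):
            extract_task(seq, "gait")

    def test_la_trial_recovers_generator_parameters(self):
        prof = DEFAULT_PROFILES["UPDRS2"]
        seq, truth = gen_la_trial(
            TrialRecipe("la_right", prof, duration=10.0, seed=7), n_poor=0
        )
        f = extract_task(seq, "la_right")
        assert f.MKAm == pytest.approx(truth["amp_mean"], rel=0.05)
        assert f.TDm == pytest.approx(truth["dur_mean"], rel=0.05)
        assert f.PM == 0

    def test_signals_returned_for_audit(self):
        seq, _ = gen_la_trial(TrialRecipe("la_right", DEFAULT_PROFILES["HC"], seed=1))
        feats, signals = extract_task(seq, "la_right", with_signals=True)
        assert "ANG_KNEE" in signals and "cycles" in signals
        assert signals["ANG_KNEE"].rate == 100.0
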