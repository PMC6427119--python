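"""Synthetic skeleton-motion generator and labeled cohorts.

Produces depth-camera-like skeleton recordings with the statistical
structure the assessment pipeline assumes, so every stage is testable
without clinical recordings:

* leg-agility trials: contiguous knee flexion/extension cycles with
  per-cycle amplitude/duration variability and optionally injected "poor
  movements" (cycles far below the trial means);
* sit-to-stand trials: a single main trunk-bending cycle plus optional
  secondary instability peaks;
* posture trials: two ten-second quasi-static phases with trunk/head bend
  offsets and a mean-reverting AR(1) center-of-mass sway whose scale grows
  in the second phase;
* cohorts: per-subject severity classes with severity-monotone parameter
  profiles, yielding both raw sequences and extracted feature tables.

Sampling emulates the device: 30 Hz with timestamp jitter and additive
joint noise.  Joint noise is temporally correlated (AR(1), ~0.3 s) and
band-limited at 2 Hz, the regime of SDK-smoothed depth-camera skeletons;
spectrally white noise of the same magnitude would swamp path-length
measures, which real trackers do not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .errors import MotionKitError
from .features import ExtractionConfig, extract_task
from .selection import FeatureTable, normalize_features, scale_for_classifier
from .skeleton import JOINT_NAMES, SkeletonSequence

# ---------------------------------------------------------------------------
# Skeleton templates (meters; subject faces +y, up is +z, subject-left -x)
# ---------------------------------------------------------------------------

_STANDING: dict[str, tuple[float, float, float]] = {
    "SpineB": (0.00, 0.00, 1.00),
    "SpineM": (0.00, 0.00, 1.22),
    "SpineS": (0.00, 0.00, 1.44),
    "Neck": (0.00, 0.00, 1.52),
    "Head": (0.00, 0.00, 1.66),
    "ShouldL": (-0.18, 0.00, 1.42),
    "ElbowL": (-0.22, 0.00, 1.14),
    "WristL": (-0.24, 0.00, 0.90),
    "HandL": (-0.24, 0.02, 0.84),
    "HandTipL": (-0.24, 0.04, 0.78),
    "ThumbL": (-0.21, 0.04, 0.84),
    "ShouldR": (0.18, 0.00, 1.42),
    "ElbowR": (0.22, 0.00, 1.14),
    "WristR": (0.24, 0.00, 0.90),
    "HandR": (0.24, 0.02, 0.84),
    "HandTipR": (0.24, 0.04, 0.78),
    "ThumbR": (0.21, 0.04, 0.84),
    "HipL": (-0.10, 0.00, 0.96),
    "KneeL": (-0.11, 0.01, 0.52),
    "AnkleL": (-0.12, 0.01, 0.08),
    "FootL": (-0.12, 0.16, 0.03),
    "HipR": (0.10, 0.00, 0.96),
    "KneeR": (0.11, 0.01, 0.52),
    "AnkleR": (0.12, 0.01, 0.08),
    "FootR": (0.12, 0.16, 0.03),
}

#: joints above the pelvis, rotated rigidly for trunk bending
_UPPER_BODY = (
    "SpineM", "SpineS", "Neck", "Head",
    "ShouldL", "ElbowL", "WristL", "HandL", "HandTipL", "ThumbL",
    "ShouldR", "ElbowR", "WristR", "HandR", "HandTipR", "ThumbR",
)

_ML_AXIS = np.array([-1.0, 0.0, 0.0])   # subject-left
_AP_AXIS = np.array([0.0, 1.0, 0.0])    # anterior
_UP_AXIS = np.array([0.0, 0.0, 1.0])

_TIBIA = 0.42          # knee->ankle length, m
_NECK_HEAD = 0.22      # SpineS->Head length, m


def _rotate_about(axis: np.ndarray, angles_rad: np.ndarray, vec: np.ndarray) -> np.ndarray:
    """Rodrigues rotation about a fixed axis, per-sample angles -> (T, 3).

    ``vec`` may be a single 3-vector or a (T, 3) stack matching the angles.
    """
    axis = axis / np.linalg.norm(axis)
    angles_rad = np.atleast_1d(np.asarray(angles_rad, dtype=float))
    vecs = np.atleast_2d(np.asarray(vec, dtype=float))
    c = np.cos(angles_rad)[:, None]
    s = np.sin(angles_rad)[:, None]
    k_cross_v = np.cross(axis, vecs)
    k_dot_v = (vecs @ axis)[:, None]
    return c * vecs + s * k_cross_v + (1 - c) * k_dot_v * axis


# ---------------------------------------------------------------------------
# Recipes and severity profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeverityProfile:
    """Per-class generator parameters; all worsening directions must be
    monotone across HC -> UPDRS3 (see ``validate_monotone``)."""

    name: str
    # leg agility
    la_amp_mean: float          # deg, mean cycle amplitude (decreases w/ severity)
    la_amp_cv: float            # relative amplitude dispersion
    la_dur_mean: float          # s, mean cycle duration (increases)
    la_dur_cv: float
    la_pm_rate: float           # expected poor movements per trial
    # arising from chair
    ac_mba: float               # deg, maximum bending angle
    ac_dur: float               # s, main bending cycle duration
    ac_extra_peak_p: float      # probability of a secondary instability peak
    # posture (clinical sign convention: forward bend negative)
    po_ftb: float               # deg, Phase1 forward trunk bending
    po_fhb: float               # deg, Phase1 forward head bending
    po_lhb: float               # deg, Phase1 lateral head bending magnitude
    po_ftb_delta: float         # deg, Phase2 - Phase1 magnitude
    po_fhb_delta: float
    po_lhb_delta: float
    # sway (AR(1) stationary SD in cm; Phase2 scale multiplier)
    sway_ap_sigma: float
    sway_ml_sigma: float
    sway_tau: float             # s, sway correlation time
    sway_phase2_scale: float


#: worsening direction of each profile field (+1 increases with severity)
_PROFILE_DIRECTIONS: dict[str, int] = {
    "la_amp_mean": -1, "la_amp_cv": +1, "la_dur_mean": +1, "la_dur_cv": +1,
    "la_pm_rate": +1, "ac_mba": +1, "ac_dur": +1, "ac_extra_peak_p": +1,
    "po_ftb": -1, "po_fhb": -1, "po_lhb": +1,
    "po_ftb_delta": +1, "po_fhb_delta": +1, "po_lhb_delta": +1,
    "sway_ap_sigma": +1, "sway_ml_sigma": +1, "sway_phase2_scale": +1,
}

CLASS_ORDER = ("HC", "UPDRS1", "UPDRS2", "UPDRS3")

DEFAULT_PROFILES: dict[str, SeverityProfile] = {
    "HC": SeverityProfile(
        "HC", la_amp_mean=36.0, la_amp_cv=0.06, la_dur_mean=0.50, la_dur_cv=0.07,
        la_pm_rate=0.0, ac_mba=16.0, ac_dur=1.0, ac_extra_peak_p=0.02,
        po_ftb=-0.5, po_fhb=-2.0, po_lhb=1.0,
        po_ftb_delta=0.30, po_fhb_delta=0.40, po_lhb_delta=0.20,
        sway_ap_sigma=0.15, sway_ml_sigma=0.12, sway_tau=1.0,
        sway_phase2_scale=1.2,
    ),
    "UPDRS1": SeverityProfile(
        "UPDRS1", la_amp_mean=29.0, la_amp_cv=0.10, la_dur_mean=0.64, la_dur_cv=0.10,
        la_pm_rate=0.6, ac_mba=24.0, ac_dur=1.7, ac_extra_peak_p=0.15,
        po_ftb=-3.0, po_fhb=-4.5, po_lhb=1.8,
        po_ftb_delta=0.35, po_fhb_delta=0.50, po_lhb_delta=0.35,
        sway_ap_sigma=0.22, sway_ml_sigma=0.25, sway_tau=1.0,
        sway_phase2_scale=1.6,
    ),
    "UPDRS2": SeverityProfile(
        "UPDRS2", la_amp_mean=23.0, la_amp_cv=0.14, la_dur_mean=0.78, la_dur_cv=0.13,
        la_pm_rate=1.2, ac_mba=30.0, ac_dur=2.4, ac_extra_peak_p=0.35,
        po_ftb=-6.0, po_fhb=-7.0, po_lhb=2.6,
        po_ftb_delta=0.45, po_fhb_delta=0.60, po_lhb_delta=0.50,
        sway_ap_sigma=0.30, sway_ml_sigma=0.40, sway_tau=1.0,
        sway_phase2_scale=2.0,
    ),
    "UPDRS3": SeverityProfile(
        "UPDRS3", la_amp_mean=17.0, la_amp_cv=0.18, la_dur_mean=0.92, la_dur_cv=0.16,
        la_pm_rate=2.0, ac_mba=36.0, ac_dur=3.1, ac_extra_peak_p=0.60,
        po_ftb=-9.0, po_fhb=-9.5, po_lhb=3.4,
        po_ftb_delta=0.60, po_fhb_delta=0.75, po_lhb_delta=0.70,
        sway_ap_sigma=0.40, sway_ml_sigma=0.55, sway_tau=1.0,
        sway_phase2_scale=2.4,
    ),
}


def validate_monotone(profiles: Mapping[str, SeverityProfile]) -> None:
    """Check every worsening-direction field is monotone across HC->UPDRS3."""
    ordered = [profiles[c] for c in CLASS_ORDER if c in profiles]
    for fname, direction in _PROFILE_DIRECTIONS.items():
        vals = [getattr(p, fname) for p in ordered]
        diffs = np.diff(vals) * direction
        if np.any(diffs < -1e-12):
            raise MotionKitError(
                f"profile field {fname!r} violates severity monotonicity: {vals}"
            )


@dataclass(frozen=True)
class TrialRecipe:
    """One synthetic trial: task, severity profile, and device parameters."""

    task: str                       # 'la_right' | 'la_left' | 'ac' | 'po'
    profile: SeverityProfile
    duration: float = 8.0           # s (posture trials use 2 x phase_duration)
    phase_duration: float = 10.0    # s, per posture phase
    rate: float = 30.0              # Hz, nominal frame rate
    jitter_sd: float = 0.003        # s, timestamp jitter SD
    noise_sd: float = 0.002         # m, joint noise SD
    noise_tau: float = 0.3          # s, joint-noise correlation time
    seed: int = 0

    def __post_init__(self) -> None:
        minimum = 5.0 if self.task.startswith("la") else 0.0
        if self.duration < minimum:
            raise MotionKitError(f"{self.task}: duration must be >= {minimum} s")
        if self.task == "po" and self.phase_duration < 5.0:
            raise MotionKitError("posture phases must be >= 5 s")


# ---------------------------------------------------------------------------
# Low-level helpers
# ---------------------------------------------------------------------------

def _timestamps(n: int, rate: float, jitter_sd: float, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) / rate + rng.normal(0.0, jitter_sd, size=n)
    t = np.sort(t)
    # enforce strict monotonicity
    eps = 1e-6
    for i in range(1, n):
        if t[i] <= t[i - 1]:
            t[i] = t[i - 1] + eps
    return t - t[0]


def _smooth_unit_noise(
    n: int,
    tau: float,
    dt: float,
    rng: np.random.Generator,
    shape_extra: tuple = (),
    cutoff_hz: float = 2.0,
) -> np.ndarray:
    """Unit-SD, band-limited mean-reverting noise paths, shape (n, *extra).

    A stationary AR(1) (discretized Ornstein-Uhlenbeck, correlation time
    ``tau``) is low-passed at ``cutoff_hz`` and renormalized to unit sample
    SD.  The band limit keeps the velocity content of the noise in the
    physiological range: a raw AR(1) has a 1/f^2 tail whose in-band part
    would dominate path-length measures at any realistic amplitude.
    """
    phi = math.exp(-dt / tau)
    eps = rng.standard_normal((n, *shape_extra))
    x = lfilter([1.0], [1.0, -phi], math.sqrt(1.0 - phi * phi) * eps, axis=0)
    nyq = 0.5 / dt
    if cutoff_hz and cutoff_hz < nyq:
        from scipy.signal import butter, sosfiltfilt

        sos = butter(2, cutoff_hz, btype="low", fs=1.0 / dt, output="sos")
        x = sosfiltfilt(sos, x, axis=0)
    sd = x.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _assemble(
    t: np.ndarray,
    trajectories: Mapping[str, np.ndarray],
    recipe: TrialRecipe,
    rng: np.random.Generator,
) -> SkeletonSequence:
    """Stack joint trajectories, add correlated joint noise, build a sequence."""
    n = t.size
    dt = 1.0 / recipe.rate
    noise = (
        recipe.noise_sd
        * _smooth_unit_noise(n, recipe.noise_tau, dt, rng,
                             shape_extra=(len(JOINT_NAMES), 3))
        if recipe.noise_sd > 0
        else np.zeros((n, len(JOINT_NAMES), 3))
    )
    joints = {}
    for k, name in enumerate(JOINT_NAMES):
        base = trajectories.get(name)
        if base is None:
            base = np.broadcast_to(np.asarray(_STANDING[name]), (n, 3))
        joints[name] = np.asarray(base, dtype=float) + noise[:, k, :]
    return SkeletonSequence(t=t, joints=joints, nominal_rate=recipe.rate)


def bump_profile(
    t: np.ndarray,
    starts: np.ndarray,
    durations: np.ndarray,
    amplitudes: np.ndarray,
    base: float,
) -> np.ndarray:
    """Piecewise raised-cosine cycle train: base + A/2 (1 - cos 2pi u)."""
    out = np.full(t.shape, float(base))
    for s, d, a in zip(starts, durations, amplitudes):
        m = (t >= s) & (t < s + d)
        u = (t[m] - s) / d
        out[m] = base + a * 0.5 * (1.0 - np.cos(2.0 * np.pi * u))
    return out


# ---------------------------------------------------------------------------
# Trial generators
# ---------------------------------------------------------------------------

_PM_AMP_FRACTION = 0.15   # poor-movement amplitude vs. normal-cycle mean
_PM_DUR_FRACTION = 0.16   # poor-movement duration vs. normal-cycle mean
_PM_DUR_FLOOR = 0.12      # s; shorter bumps are unresolvable at the 10 Hz band


def gen_la_trial(
    recipe: TrialRecipe, n_poor: int | None = None
) -> tuple[SkeletonSequence, dict]:
    """Leg-agility trial: knee flexion/extension cycle train.

    The hip and knee stay fixed while the ankle swings about the knee so
    the knee angle follows a raised-cosine cycle train whose per-cycle
    amplitudes and durations are drawn from the severity profile.
    ``n_poor`` forces an exact number of injected poor movements (default:
    Poisson with the profile's rate).  Ground truth records the per-cycle
    parameters.
    """
    p = recipe.profile
    if p.la_amp_mean > 140.0:
        raise MotionKitError("amplitude > 140 deg is geometrically infeasible")
    rng = np.random.default_rng(recipe.seed)
    lead = 0.5

    durations, amplitudes = [], []
    total = lead
    while total + p.la_dur_mean < recipe.duration - lead:
        d = max(0.25, rng.normal(p.la_dur_mean, p.la_dur_cv * p.la_dur_mean))
        a = min(140.0, max(2.0, rng.normal(p.la_amp_mean, p.la_amp_cv * p.la_amp_mean)))
        durations.append(d)
        amplitudes.append(a)
        total += d
    if not durations:
        raise MotionKitError("trial too short for a single cycle")

    if n_poor is None:
        n_poor = int(rng.poisson(p.la_pm_rate))
    n_poor = min(n_poor, max(0, len(durations) - 2))
    pm_positions = sorted(
        rng.choice(np.arange(1, len(durations)), size=n_poor, replace=False)
    ) if n_poor else []
    mean_a, mean_d = float(np.mean(amplitudes)), float(np.mean(durations))
    for offset, pos in enumerate(pm_positions):
        durations.insert(pos + offset, max(_PM_DUR_FLOOR, _PM_DUR_FRACTION * mean_d))
        amplitudes.insert(pos + offset, _PM_AMP_FRACTION * mean_a)

    durations = np.asarray(durations)
    amplitudes = np.asarray(amplitudes)
    starts = lead + np.concatenate([[0.0], np.cumsum(durations[:-1])])
    total_time = starts[-1] + durations[-1] + lead

    n = int(round(total_time * recipe.rate))
    t = _timestamps(n, recipe.rate, recipe.jitter_sd, rng)
    base_angle = 90.0
    theta = bump_profile(t, starts, durations, amplitudes, base_angle)

    side = "L" if recipe.task == "la_left" else "R"
    hip = np.array([0.10 * (1 if side == "R" else -1), 0.00, 0.50])
    knee = hip + np.array([0.0, 0.45, 0.0])
    u = (hip - knee) / np.linalg.norm(hip - knee)   # knee->hip
    w = np.array([0.0, 0.0, -1.0])                  # down
    rad = np.radians(theta)
    ankle = knee + _TIBIA * (np.cos(rad)[:, None] * u + np.sin(rad)[:, None] * w)
    foot = ankle + np.array([0.0, 0.10, -0.03])

    seated = {
        "SpineB": (0.0, 0.0, 0.62), "SpineM": (0.0, 0.0, 0.84),
        "SpineS": (0.0, 0.0, 1.06), "Neck": (0.0, 0.0, 1.14),
        "Head": (0.0, 0.0, 1.28),
        "ShouldL": (-0.18, 0.0, 1.04), "ShouldR": (0.18, 0.0, 1.04),
        "HipL": (-0.10, 0.0, 0.50), "HipR": (0.10, 0.0, 0.50),
    }
    traj = {
        name: np.broadcast_to(np.asarray(pos), (n, 3))
        for name, pos in seated.items()
    }
    traj[f"Hip{side}"] = np.broadcast_to(hip, (n, 3))
    traj[f"Knee{side}"] = np.broadcast_to(knee, (n, 3))
    traj[f"Ankle{side}"] = ankle
    traj[f"Foot{side}"] = foot

    truth = {
        "task": recipe.task,
        "base_angle": base_angle,
        "amplitudes": amplitudes.tolist(),
        "durations": durations.tolist(),
        "starts": starts.tolist(),
        "n_cycles": int(len(durations)),
        "n_poor": int(n_poor),
        "amp_mean": float(np.mean(amplitudes)),
        "dur_mean": float(np.mean(durations)),
    }
    return _assemble(t, traj, recipe, rng), truth


def gen_ac_trial(
    recipe: TrialRecipe, n_extra: int | None = None
) -> tuple[SkeletonSequence, dict]:
    """Sit-to-stand trial: one main trunk-bending cycle, optional extras.

    The upper body rotates rigidly about the pelvis in the sagittal plane;
    the main raised-cosine bend carries the profile's maximum bending angle
    and duration, and ``n_extra`` secondary peaks (default Bernoulli with
    the profile's probability) emulate hesitation/instability events after
    standing.
    """
    p = recipe.profile
    rng = np.random.default_rng(recipe.seed)
    if n_extra is None:
        n_extra = int(rng.random() < p.ac_extra_peak_p)

    extra_amp, extra_dur, gap = 6.0, 0.8, 0.4
    starts = [1.0]
    durations = [p.ac_dur]
    amplitudes = [p.ac_mba]
    cursor = 1.0 + p.ac_dur + gap
    for _ in range(n_extra):
        starts.append(cursor)
        durations.append(extra_dur)
        amplitudes.append(extra_amp)
        cursor += extra_dur + gap
    total_time = max(recipe.duration, cursor + 1.0)

    n = int(round(total_time * recipe.rate))
    t = _timestamps(n, recipe.rate, recipe.jitter_sd, rng)
    base = 2.0
    theta = bump_profile(t, np.array(starts), np.array(durations), np.array(amplitudes), base)

    rad = np.radians(theta)
    pelvis = np.asarray(_STANDING["SpineB"])
    traj = {}
    for name in _UPPER_BODY:
        offset = np.asarray(_STANDING[name]) - pelvis
        traj[name] = pelvis + _rotate_about(_ML_AXIS, rad, offset)
    truth = {
        "task": "ac",
        "MBA": float(p.ac_mba),
        "TD": float(p.ac_dur),
        "n_extra": int(n_extra),
        "NPeaks": 1 + int(n_extra),
        "base_angle": base,
        "starts": list(starts),
        "durations": list(durations),
        "amplitudes": list(amplitudes),
    }
    return _assemble(t, traj, recipe, rng), truth


def gen_posture_trial(recipe: TrialRecipe) -> tuple[SkeletonSequence, dict]:
    """Posture/sway trial: two quasi-static phases with AR(1) CoM sway.

    Phase 1 holds the profile's trunk/head bending offsets; Phase 2 shifts
    them by the profile deltas (a voluntary posture correction) and scales
    the sway process by the Phase-2 multiplier.  Ground truth stores the
    signed angle targets per phase and the realized sway paths in cm.
    """
    p = recipe.profile
    rng = np.random.default_rng(recipe.seed)
    half = recipe.phase_duration
    total_time = 2.0 * half
    n = int(round(total_time * recipe.rate))
    t = _timestamps(n, recipe.rate, recipe.jitter_sd, rng)

    # signed targets per phase (clinical convention: forward bend negative)
    lhb_sign = 1.0 if rng.random() < 0.5 else -1.0
    ftb = (p.po_ftb, p.po_ftb + p.po_ftb_delta)          # correction: less bent
    fhb = (p.po_fhb, p.po_fhb + p.po_fhb_delta)
    lhb = (lhb_sign * p.po_lhb, lhb_sign * (p.po_lhb + p.po_lhb_delta))

    def phase_profile(v1: float, v2: float) -> np.ndarray:
        out = np.where(t < half, v1, v2).astype(float)
        ramp = 0.4  # smooth the transition to avoid a spurious velocity spike
        m = np.abs(t - half) < ramp
        u = (t[m] - (half - ramp)) / (2 * ramp)
        out[m] = v1 + (v2 - v1) * 0.5 * (1 - np.cos(np.pi * np.clip(u, 0, 1)))
        return out

    beta = np.radians(-phase_profile(*ftb))      # forward trunk rotation, rad
    gamma = np.radians(-np.array(fhb))           # head-on-spine forward rotation
    lam = np.radians(np.array(lhb))
    gamma_t = phase_profile(gamma[0], gamma[1])
    lam_t = phase_profile(lam[0], lam[1])

    # sway translation (cm -> m), applied to the whole body
    dt = 1.0 / recipe.rate
    sd_scale = np.where(t < half, 1.0, p.sway_phase2_scale)
    ap_cm = p.sway_ap_sigma * sd_scale * _smooth_unit_noise(n, p.sway_tau, dt, rng)
    ml_cm = p.sway_ml_sigma * sd_scale * _smooth_unit_noise(n, p.sway_tau, dt, rng)
    sway = np.column_stack([ml_cm, ap_cm, np.zeros(n)]) / 100.0

    pelvis = np.asarray(_STANDING["SpineB"])
    traj = {}
    for name in _UPPER_BODY:
        offset = np.asarray(_STANDING[name]) - pelvis
        traj[name] = pelvis + _rotate_about(_ML_AXIS, beta, offset)
    # head: additional rotation relative to the (already bent) spine
    spine_s = traj["SpineS"]
    spine_dir = _rotate_about(_ML_AXIS, beta, _UP_AXIS)
    # compose head-on-spine tilts: sagittal (forward) then lateral (left +)
    head_dir = _rotate_about(_AP_AXIS, -lam_t,
                             _rotate_about(_ML_AXIS, gamma_t, spine_dir))
    traj["Head"] = spine_s + _NECK_HEAD * head_dir
    traj["Neck"] = spine_s + 0.36 * _NECK_HEAD * head_dir

    for name in JOINT_NAMES:
        base = traj.get(name)
        if base is None:
            base = np.broadcast_to(np.asarray(_STANDING[name]), (n, 3))
        traj[name] = np.asarray(base) + sway

    truth = {
        "task": "po",
        "FTB": ftb, "FHB": fhb, "LHB_signed": lhb,
        "LHB": (abs(lhb[0]), abs(lhb[1])),
        "sway_ap_sigma": (p.sway_ap_sigma, p.sway_ap_sigma * p.sway_phase2_scale),
        "sway_ml_sigma": (p.sway_ml_sigma, p.sway_ml_sigma * p.sway_phase2_scale),
        "ap_cm": ap_cm, "ml_cm": ml_cm, "t": t,
        "phase_duration": half,
    }
    return _assemble(t, traj, recipe, rng), truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

DEFAULT_COHORT: dict[str, int] = {"HC": 12, "UPDRS1": 5, "UPDRS2": 5, "UPDRS3": 4}

#: features entering the default per-task tables
TASK_FEATURES: dict[str, tuple[str, ...]] = {
    "la_right": ("MKAm", "MKAv", "TDm", "TDv", "SPm", "PM"),
    "ac": ("MBA", "TD", "SPm", "NPeaks"),
    "po": ("FTB", "FTB_d", "FHB", "FHB_d", "LHB", "LHB_d"),
    "ps_com": ("APr", "APt", "MLt", "APv", "MLv", "SwayArea"),
}

_MAGNITUDE_FIELDS = tuple(
    f for f in _PROFILE_DIRECTIONS
    if f not in ("la_pm_rate", "ac_extra_peak_p")
)


def _jitter_profile(
    p: SeverityProfile, rng: np.random.Generator, cv: float
) -> SeverityProfile:
    """Subject-level variability: lognormal multipliers on magnitude fields."""
    changes = {}
    for fname in _MAGNITUDE_FIELDS:
        v = getattr(p, fname)
        changes[fname] = v * float(rng.lognormal(0.0, cv))
    return replace(p, **changes)


@dataclass
class CohortData:
    """A labeled synthetic cohort: per-task feature tables plus provenance."""

    tables: dict[str, FeatureTable]
    classes: np.ndarray            # 'HC' / 'UPDRS1' / ...
    class_codes: np.ndarray        # 0..3
    pigd: np.ndarray               # PIGD-style subscale sums
    sequences: dict[str, list[SkeletonSequence]] | None
    truths: dict[str, list[dict]]
    seed: int


def gen_cohort(
    n_per_class: Mapping[str, int] | None = None,
    profiles: Mapping[str, SeverityProfile] | None = None,
    seed: int = 0,
    subject_cv: float = 0.06,
    keep_sequences: bool = True,
    config: ExtractionConfig | None = None,
    la_duration: float = 8.0,
) -> CohortData:
    """Generate a labeled multi-task cohort and extract its feature tables.

    Each subject gets a severity class, a subject-level jitter of the class
    profile, and one trial per task (the posture trial feeds both the Po
    and the sway feature tables).  Reproducible from ``seed``; the default
    class sizes mirror a small clinical cohort (12 HC + 14 PD split 5/5/4).
    """
    n_per_class = dict(n_per_class or DEFAULT_COHORT)
    profiles = dict(profiles or DEFAULT_PROFILES)
    validate_monotone(profiles)
    cfg = config or ExtractionConfig()
    rng = np.random.default_rng(seed)

    rows: dict[str, list[dict]] = {k: [] for k in TASK_FEATURES}
    sequences: dict[str, list[SkeletonSequence]] = {k: [] for k in ("la_right", "ac", "po")}
    truths: dict[str, list[dict]] = {k: [] for k in ("la_right", "ac", "po")}
    classes, codes, pigd = [], [], []

    for cls in CLASS_ORDER:
        for _ in range(n_per_class.get(cls, 0)):
            prof = _jitter_profile(profiles[cls], rng, subject_cv)
            code = CLASS_ORDER.index(cls)
            sub_seed = int(rng.integers(0, 2**31 - 1))

            la_seq, la_truth = gen_la_trial(replace_recipe(
                prof, "la_right", duration=la_duration, seed=sub_seed))
            ac_seq, ac_truth = gen_ac_trial(replace_recipe(
                prof, "ac", duration=8.0, seed=sub_seed + 1))
            po_seq, po_truth = gen_posture_trial(replace_recipe(
                prof, "po", seed=sub_seed + 2))

            rows["la_right"].append(extract_task(la_seq, "la_right", cfg).as_dict())
            rows["ac"].append(extract_task(ac_seq, "ac", cfg).as_dict())
            rows["po"].append(extract_task(po_seq, "po", cfg).as_dict())
            rows["ps_com"].append(extract_task(po_seq, "ps_com", cfg).as_dict())

            if keep_sequences:
                sequences["la_right"].append(la_seq)
                sequences["ac"].append(ac_seq)
                sequences["po"].append(po_seq)
            truths["la_right"].append(la_truth)
            truths["ac"].append(ac_truth)
            truths["po"].append(po_truth)

            classes.append(cls)
            codes.append(code)
            if cls == "HC":
                pigd.append(int(rng.integers(0, 2)))
            else:
                pigd.append(int(np.clip(4 * code + rng.integers(-2, 3), 1, 16)))

    classes = np.asarray(classes)
    codes = np.asarray(codes)
    pigd = np.asarray(pigd, dtype=float)
    group = np.where(classes == "HC", "HC", "PD")

    tables = {}
    for task, cols in TASK_FEATURES.items():
        df = pd.DataFrame(rows[task])[list(cols)].astype(float)
        score = pigd if task == "ps_com" else codes.astype(float)
        tables[task] = FeatureTable(df, group, score)

    return CohortData(
        tables=tables, classes=classes, class_codes=codes, pigd=pigd,
        sequences=sequences if keep_sequences else None,
        truths=truths, seed=seed,
    )


def replace_recipe(profile: SeverityProfile, task: str, **kw) -> TrialRecipe:
    """Convenience constructor for a TrialRecipe bound to a profile."""
    return TrialRecipe(task=task, profile=profile, **kw)


def classification_inputs(
    table: FeatureTable, problem: str = "binary", tertile_labels: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized + [0,1]-scaled classifier inputs from a cohort table.

    ``problem='binary'`` returns all rows with 0/1 HC/PD labels;
    ``'multiclass'`` returns the PD rows with ordinal class labels
    (scaling is still fitted on the full table, HC included).  With
    ``tertile_labels`` the multiclass labels are tertile bins of the score
    (used for subscale-sum scores that have no native 3-class coding).
    Columns whose severity-monotone [0,1] map is undefined on this sample
    (no spread beyond the healthy reference) are dropped.
    """
    norm = normalize_features(table)
    usable = []
    for col in norm.names:
        p = norm.data[col].to_numpy(dtype=float)
        if col in norm.exclude_normalize:
            if p.max() > 0:
                usable.append(col)
        elif p.max() > 1.0 + 1e-12 or p.min() < 1.0 - 1e-12:
            usable.append(col)
    norm = norm.subset(usable)
    X, _, _ = scale_for_classifier(norm)
    Xv = X.to_numpy(dtype=float)
    if problem == "binary":
        y = (table.group == "PD").astype(int)
        return Xv, y
    if problem == "multiclass":
        mask = table.group == "PD"
        s = table.score[mask]
        if tertile_labels:
            # balanced rank tertiles (quantile cuts can strand a class
            # with a single member when the score distribution is lumpy)
            order = np.argsort(s, kind="stable")
            y = np.empty(len(s), dtype=int)
            thirds = np.array_split(order, 3)
            for label, idx in enumerate(thirds, start=1):
                y[idx] = label
        else:
            y = np.round(s).astype(int)
        return Xv[mask], y
    raise ValueError("problem must be 'binary' or 'multiclass'")
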