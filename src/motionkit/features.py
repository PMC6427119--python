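"""Movement-cycle segmentation and per-task kinematic feature vectors.

Tasks follow the standard lower-limb and postural motor items:

* LA (leg agility): repeated knee flexion/extension; features summarize
  per-cycle amplitude, duration and speed plus a "poor movement" count.
* AC (arising from chair): a single trunk-bending cycle with possible
  secondary peaks from hesitations/instability.
* Po (posture): quasi-static trunk/head bending angles in two ten-second
  phases and their phase-to-phase variations.
* PS_COM (postural sway): range, path length, velocity and convex-hull
  area of the transverse-plane CoM excursion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks
from scipy.spatial import ConvexHull, QhullError

from .errors import (
    IncompleteSitToStandError,
    InsufficientDataError,
    InsufficientMovementError,
    MissingJointError,
)
from .kinematics import (
    BodyFrame,
    ComTrajectory,
    SegmentWeights,
    angular_velocity,
    build_body_frame,
    com_trajectory,
    head_bend_angles,
    segment_angle,
    trunk_angle,
    trunk_angle_sagittal,
)
from .skeleton import (
    AngleSignal,
    FILTER_CUTOFF,
    FILTER_ORDER,
    REQUIRED_JOINTS,
    RESAMPLE_RATE,
    SkeletonSequence,
    resample_and_filter,
    series_from_sequence,
)


# ---------------------------------------------------------------------------
# Cycle segmentation
# ---------------------------------------------------------------------------

@dataclass
class MovementCycle:
    """One minimum-maximum-minimum flexion/extension cycle."""

    i_min1: int
    i_max: int
    i_min2: int
    amplitude: float   # degrees, peak-to-peak within the cycle
    duration: float    # seconds
    peak_speed: float  # degrees/s, max |angular velocity| within the cycle

    def __post_init__(self) -> None:
        assert self.i_min1 < self.i_max < self.i_min2
        assert self.amplitude >= 0 and self.duration > 0


def segment_cycles(
    sig: AngleSignal,
    min_prominence: float = 1.0,
    min_duration: float = 0.1,
    velocity: np.ndarray | None = None,
) -> list[MovementCycle]:
    """Split an angle signal into min-max-min movement cycles.

    Maxima are detected with prominence >= ``min_prominence`` (degrees);
    each cycle runs from the deepest minimum before its peak to the deepest
    minimum after it, adjacent cycles sharing the boundary minimum.  Signal
    endpoints may serve as boundary minima only when the signal has dropped
    at least ``min_prominence`` below the peak there, so a trailing maximum
    without a closing descent does not form a cycle.  Cycles shorter than
    ``min_duration`` seconds are treated as noise and discarded (the
    prominence and duration floors suppress noise-born extrema).
    """
    v = sig.values
    n = v.size
    if n < 4:
        return []
    maxima, _ = find_peaks(v, prominence=min_prominence)
    if maxima.size == 0:
        return []
    if velocity is None:
        velocity = angular_velocity(sig)

    # candidate boundary minima: interior local minima plus the endpoints
    minima, _ = find_peaks(-v)
    candidates = np.unique(np.concatenate([[0, n - 1], minima]))

    cycles: list[MovementCycle] = []
    bounds = np.concatenate([[-1], maxima, [n]])
    # boundary cost trades depth against distance from the peak: among the
    # near-equal noise dips of a flat baseline the nearest one wins, while
    # a genuinely deeper minimum (degrees below) always wins over proximity
    proximity_rate = 2.0 * min_prominence  # degrees per second
    for j, m in enumerate(maxima):
        lo, hi = bounds[j], bounds[j + 2]  # previous max (excl) .. next max (excl)

        def boundary(cands: np.ndarray, peak: int) -> int | None:
            if cands.size == 0:
                return None
            cost = v[cands] + proximity_rate * np.abs(sig.t[cands] - sig.t[peak])
            return int(cands[np.argmin(cost)])

        left = boundary(candidates[(candidates > lo) & (candidates < m)], m)
        right = boundary(candidates[(candidates > m) & (candidates < hi)], m)
        # endpoints only count if the signal actually descended there
        if left in (0,) and v[m] - v[left] < min_prominence:
            left = None
        if right == n - 1 and v[m] - v[right] < min_prominence:
            right = None
        if left is None or right is None:
            continue
        duration = float(sig.t[right] - sig.t[left])
        amplitude = float(v[m] - v[left:right + 1].min())
        if duration < min_duration or amplitude < min_prominence:
            continue
        cycles.append(
            MovementCycle(
                i_min1=left,
                i_max=int(m),
                i_min2=right,
                amplitude=amplitude,
                duration=duration,
                peak_speed=float(np.max(np.abs(velocity[left:right + 1]))),
            )
        )
    return cycles


# ---------------------------------------------------------------------------
# Feature vectors
# ---------------------------------------------------------------------------

@dataclass
class LAFeatures:
    """Leg-agility parameters.

    MKAm/MKAv: mean and normalized dispersion (coefficient of variation) of
    per-cycle peak-to-peak knee-angle amplitudes; TDm/TDv: same for cycle
    durations; SPm: mean of per-cycle speed maxima (deg/s); PM: number of
    "poor movements" — cycles whose amplitude AND duration are both below
    25% of the trial means.
    """

    MKAm: float
    MKAv: float
    TDm: float
    TDv: float
    SPm: float
    PM: int

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class ACFeatures:
    """Sit-to-stand parameters: maximum bending angle (deg), duration of the
    main bending cycle (s), mean absolute trunk speed within it (deg/s),
    and the number of detected bending peaks (secondary peaks flag
    hesitations or instability events)."""

    MBA: float
    TD: float
    SPm: float
    NPeaks: int

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class PoFeatures:
    """Posture parameters: Phase-1 mean trunk/head bending angles (forward
    bend negative, lateral head bend as absolute value) and the absolute
    Phase2-Phase1 variations."""

    FTB: float
    FHB: float
    LHB: float
    FTB_d: float
    FHB_d: float
    LHB_d: float

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class SwayFeatures:
    """Postural-sway parameters in the transverse plane (cm, cm/s, cm^2)."""

    APr: float
    MLr: float
    APt: float
    MLt: float
    APv: float
    MLv: float
    SwayArea: float

    def as_dict(self) -> dict:
        return asdict(self)


def la_features(
    cycles: Sequence[MovementCycle],
    poor_fraction: float = 0.25,
    include_poor_in_means: bool = True,
) -> LAFeatures:
    """Leg-agility feature vector from a cycle list.

    The poor-movement rule compares each cycle against ``poor_fraction`` of
    the trial-mean amplitude (MKAm) and duration (TDm); flagged cycles are
    included in the means by default (``include_poor_in_means=False``
    excludes them and recomputes the means once).
    """
    if not cycles:
        raise InsufficientMovementError("no movement cycle detected")
    amps = np.array([c.amplitude for c in cycles])
    durs = np.array([c.duration for c in cycles])
    speeds = np.array([c.peak_speed for c in cycles])

    mkam, tdm = float(amps.mean()), float(durs.mean())
    poor = (amps < poor_fraction * mkam) & (durs < poor_fraction * tdm)
    if not include_poor_in_means and np.any(poor):
        keep = ~poor
        mkam, tdm = float(amps[keep].mean()), float(durs[keep].mean())
        speeds = speeds[keep]
        amps_for_var, durs_for_var = amps[keep], durs[keep]
    else:
        amps_for_var, durs_for_var = amps, durs

    return LAFeatures(
        MKAm=mkam,
        MKAv=float(amps_for_var.std() / mkam) if mkam > 0 else 0.0,
        TDm=tdm,
        TDv=float(durs_for_var.std() / tdm) if tdm > 0 else 0.0,
        SPm=float(speeds.mean()),
        PM=int(poor.sum()),
    )


def ac_features(
    sig: AngleSignal,
    velocity: np.ndarray | None = None,
    min_prominence: float = 1.0,
    min_duration: float = 0.1,
) -> ACFeatures:
    """Sit-to-stand feature vector from the trunk-angle signal."""
    if velocity is None:
        velocity = angular_velocity(sig)
    cycles = segment_cycles(sig, min_prominence, min_duration, velocity)
    if not cycles:
        raise IncompleteSitToStandError("no trunk-bending cycle detected")
    main = max(cycles, key=lambda c: c.amplitude)
    seg = slice(main.i_min1, main.i_min2 + 1)
    return ACFeatures(
        MBA=float(main.amplitude),
        TD=float(main.duration),
        SPm=float(np.mean(np.abs(velocity[seg]))),
        NPeaks=len(cycles),
    )


def po_features(
    phase1: Mapping[str, AngleSignal],
    phase2: Mapping[str, AngleSignal],
    min_phase_duration: float = 5.0,
) -> PoFeatures:
    """Posture feature vector from per-phase angle signals.

    Expects keys ``ANG_TRUNK``, ``ANG_FORHEAD``, ``ANG_LATHEAD`` in each
    phase, already in the clinical sign convention (forward bend negative).
    LHB is the absolute lateral head bend; the variation terms are absolute
    differences of the phase means.
    """
    for label, phase in (("phase1", phase1), ("phase2", phase2)):
        for key in ("ANG_TRUNK", "ANG_FORHEAD", "ANG_LATHEAD"):
            if key not in phase:
                raise KeyError(f"{label} missing {key}")
            sig = phase[key]
            if sig.t[-1] - sig.t[0] < min_phase_duration:
                raise InsufficientDataError(
                    f"{label}/{key}: phase shorter than {min_phase_duration} s"
                )
    ftb1 = float(np.mean(phase1["ANG_TRUNK"].values))
    ftb2 = float(np.mean(phase2["ANG_TRUNK"].values))
    fhb1 = float(np.mean(phase1["ANG_FORHEAD"].values))
    fhb2 = float(np.mean(phase2["ANG_FORHEAD"].values))
    lhb1 = abs(float(np.mean(phase1["ANG_LATHEAD"].values)))
    lhb2 = abs(float(np.mean(phase2["ANG_LATHEAD"].values)))
    return PoFeatures(
        FTB=ftb1,
        FHB=fhb1,
        LHB=lhb1,
        FTB_d=abs(ftb2 - ftb1),
        FHB_d=abs(fhb2 - fhb1),
        LHB_d=abs(lhb2 - lhb1),
    )


def sway_features(com: ComTrajectory) -> SwayFeatures:
    """Range, path length, mean velocity and convex-hull area of the sway."""
    if len(com) < 2 or com.duration <= 0:
        raise InsufficientDataError("need >= 2 sway samples with positive duration")
    ap, ml = com.ap, com.ml
    apt = float(np.sum(np.abs(np.diff(ap))))
    mlt = float(np.sum(np.abs(np.diff(ml))))
    pts = np.column_stack([ap, ml])
    try:
        area = float(ConvexHull(pts).volume)  # 2-D hull: .volume is the area
    except (QhullError, ValueError):
        area = 0.0  # degenerate (collinear / coincident) sway path
    return SwayFeatures(
        APr=float(np.ptp(ap)),
        MLr=float(np.ptp(ml)),
        APt=apt,
        MLt=mlt,
        APv=apt / com.duration,
        MLv=mlt / com.duration,
        SwayArea=area,
    )


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class ExtractionConfig:
    """Tunable knobs of the extraction pipeline.

    ``vertical`` is the up direction used when no floor plane is available
    (the camera is assumed roughly level); ``phase_split`` is the Po/PS_COM
    phase boundary as a fraction of the recording.
    """

    target_rate: float = RESAMPLE_RATE
    cutoff: float = FILTER_CUTOFF
    filter_order: int = FILTER_ORDER
    min_prominence: float = 1.0
    ac_min_prominence: float = 3.0  # trunk peaks below this are not clinically
    #                                 relevant hesitations, just tracker noise
    min_cycle_duration: float = 0.1
    poor_fraction: float = 0.25
    include_poor_in_means: bool = True
    phase_split: float = 0.5
    vertical: tuple[float, float, float] = (0.0, 0.0, 1.0)
    weights: SegmentWeights = field(default_factory=SegmentWeights)


TASKS = ("la_left", "la_right", "ac", "po", "ps_com")


def extract_task(
    seq: SkeletonSequence,
    task: str,
    config: ExtractionConfig | None = None,
    with_signals: bool = False,
):
    """Run the full pipeline for one task on a skeleton sequence.

    Preprocesses (per-frame angles on the raw jittered timestamps, then
    resampling + zero-phase filtering of the angle signals), segments
    cycles or projects the CoM, and returns the task's feature vector.
    With ``with_signals=True`` returns ``(features, signals)`` where
    ``signals`` holds the intermediate series for audit.
    """
    cfg = config or ExtractionConfig()
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    try:
        seq.require(REQUIRED_JOINTS[task])
    except MissingJointError as exc:
        raise MissingJointError(exc.joints) from None

    signals: dict[str, object] = {}
    try:
        if task in ("la_left", "la_right"):
            feats = _extract_la(seq, task, cfg, signals)
        elif task == "ac":
            feats = _extract_ac(seq, cfg, signals)
        elif task == "po":
            feats = _extract_po(seq, cfg, signals)
        else:
            feats = _extract_ps_com(seq, cfg, signals)
    except Exception as exc:
        exc.args = (f"[task {task}] {exc.args[0] if exc.args else exc}",) + exc.args[1:]
        raise
    return (feats, signals) if with_signals else feats


def _resample(cfg: ExtractionConfig, t, v, name):
    return resample_and_filter(
        t, v, cfg.target_rate, cfg.cutoff, cfg.filter_order, name=name
    )


def _extract_la(seq, task, cfg, signals):
    side = "L" if task == "la_left" else "R"
    t, knee = series_from_sequence(
        seq, (f"Hip{side}", f"Knee{side}", f"Ankle{side}"), segment_angle
    )
    sig = _resample(cfg, t, knee, "ANG_KNEE")
    vel = angular_velocity(sig)
    cycles = segment_cycles(sig, cfg.min_prominence, cfg.min_cycle_duration, vel)
    signals.update(ANG_KNEE=sig, velocity=vel, cycles=cycles)
    return la_features(cycles, cfg.poor_fraction, cfg.include_poor_in_means)


def _extract_ac(seq, cfg, signals):
    vertical = np.asarray(cfg.vertical, dtype=float)
    t, trunk = series_from_sequence(
        seq, ("SpineS", "SpineB"),
        lambda s, b: trunk_angle(s, b, vertical),
    )
    sig = _resample(cfg, t, trunk, "ANG_TRUNK")
    vel = angular_velocity(sig)
    signals.update(ANG_TRUNK=sig, velocity=vel)
    return ac_features(sig, vel, cfg.ac_min_prominence, cfg.min_cycle_duration)


def _phase_bounds(seq: SkeletonSequence, cfg: ExtractionConfig):
    t0, t1 = float(seq.t[0]), float(seq.t[-1])
    split = t0 + cfg.phase_split * (t1 - t0)
    return (t0, split), (split, t1)


def _po_body_frame(seq: SkeletonSequence, cfg: ExtractionConfig) -> BodyFrame:
    (p1_lo, p1_hi), _ = _phase_bounds(seq, cfg)
    pose = seq.median_pose(("ShouldL", "ShouldR", "SpineB", "SpineS"), t_max=p1_hi)
    return build_body_frame(pose, vertical=np.asarray(cfg.vertical, dtype=float))


def _extract_po(seq, cfg, signals):
    frame = _po_body_frame(seq, cfg)
    # clinical sign convention: forward (ventral) bending is negative
    t, trunk = series_from_sequence(
        seq, ("SpineS", "SpineB"),
        lambda s, b: -trunk_angle_sagittal(s, b, frame),
    )
    _, fwd_lat = series_from_sequence(
        seq, ("Head", "SpineS", "SpineB"),
        lambda h, s, b: np.stack(head_bend_angles(h, s, b, frame), axis=-1),
    )
    sig_trunk = _resample(cfg, t, trunk, "ANG_TRUNK")
    sig_fwd = _resample(cfg, t, -fwd_lat[:, 0], "ANG_FORHEAD")
    sig_lat = _resample(cfg, t, fwd_lat[:, 1], "ANG_LATHEAD")
    (p1_lo, p1_hi), (p2_lo, p2_hi) = _phase_bounds(seq, cfg)
    phase1 = {s.name: s.crop(p1_lo, p1_hi) for s in (sig_trunk, sig_fwd, sig_lat)}
    phase2 = {s.name: s.crop(p2_lo, p2_hi) for s in (sig_trunk, sig_fwd, sig_lat)}
    signals.update(
        body_frame=frame, ANG_TRUNK=sig_trunk, ANG_FORHEAD=sig_fwd,
        ANG_LATHEAD=sig_lat, phase1=phase1, phase2=phase2,
    )
    return po_features(phase1, phase2)


def _extract_ps_com(seq, cfg, signals):
    frame = _po_body_frame(seq, cfg)
    com = com_trajectory(seq, frame, cfg.weights)
    # resample + low-pass the sway components like any other pipeline signal
    ap = _resample(cfg, com.t, com.ap, "COM_AP")
    ml = _resample(cfg, com.t, com.ml, "COM_ML")
    smooth = ComTrajectory(t=ap.t, com3d=np.empty((len(ap), 0)),
                           ap=ap.values, ml=ml.values)
    (p1_lo, p1_hi), (p2_lo, p2_hi) = _phase_bounds(seq, cfg)
    phase1 = smooth.crop(p1_lo, p1_hi)
    phase2 = smooth.crop(p2_lo, p2_hi)
    feats = sway_features(smooth)
    signals.update(
        body_frame=frame, com=com, com_filtered=smooth,
        phase1=sway_features(phase1), phase2=sway_features(phase2),
    )
    signals["phase_delta"] = {
        k: signals["phase2"].as_dict()[k] - signals["phase1"].as_dict()[k]
        for k in ("APr", "MLr", "APt", "MLt", "APv", "MLv", "SwayArea")
    }
    return feats
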