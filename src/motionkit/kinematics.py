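"""Geometric core: floor plane, body frame, segment angles, center of mass.

All angles are computed from inner products of unit vectors along body
segments, in degrees.  The body center of mass C_b is the weighted average
of six segment centroids (midpoints of joint pairs), with weights from
standard anthropometric segment-mass tables, renormalized to sum to one.
For sway analysis only the transverse-plane (AP/ML) components of C_b are
used, in centimeters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import (
    DegenerateGeometryError,
    InsufficientDataError,
    MissingJointError,
    NoFloorFoundError,
)
from .skeleton import AngleSignal, SkeletonSequence

Vector = np.ndarray


def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v, axis=-1, keepdims=v.ndim > 1)
    if np.any(n < 1e-12):
        raise DegenerateGeometryError(f"zero-length {what}")
    return v / n


# ---------------------------------------------------------------------------
# Floor plane (RANSAC)
# ---------------------------------------------------------------------------

@dataclass
class FloorPlane:
    """Plane ``normal . x = offset`` with the normal oriented upward."""

    normal: np.ndarray
    offset: float

    def __post_init__(self) -> None:
        self.normal = _unit(np.asarray(self.normal, dtype=float), "plane normal")
        self.offset = float(self.offset)

    def distance(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.normal - self.offset

    def to_dict(self) -> dict:
        return {"normal": self.normal.tolist(), "offset": self.offset}


def fit_floor_plane(
    points: np.ndarray,
    up_prior: np.ndarray,
    feet: np.ndarray | None = None,
    inlier_threshold: float = 0.01,
    n_iterations: int = 500,
    min_inlier_fraction: float = 0.30,
    feet_tolerance: float = 0.10,
    seed: int | np.random.Generator | None = 0,
) -> FloorPlane:
    """RANSAC plane fit to a 3D point cloud, used to estimate the vertical.

    The winning plane maximizes the number of points within
    ``inlier_threshold`` (meters) and is refined by a least-squares (SVD)
    fit on its inliers.  The normal is flipped to agree with ``up_prior``.
    If foot positions are supplied the plane must pass within
    ``feet_tolerance`` of each of them, otherwise it is rejected.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or points.shape[0] < 50:
        raise InsufficientDataError("need a (N>=50, 3) point cloud")
    up = _unit(np.asarray(up_prior, dtype=float), "up prior")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    n_pts = points.shape[0]
    best_count, best = 0, None
    for _ in range(n_iterations):
        idx = rng.choice(n_pts, size=3, replace=False)
        p0, p1, p2 = points[idx]
        normal = np.cross(p1 - p0, p2 - p0)
        norm = np.linalg.norm(normal)
        if norm < 1e-12:  # collinear sample
            continue
        normal = normal / norm
        dist = points @ normal - normal @ p0
        count = int(np.sum(np.abs(dist) < inlier_threshold))
        if count > best_count:
            best_count, best = count, (normal, float(normal @ p0))
    if best is None or best_count < min_inlier_fraction * n_pts:
        raise NoFloorFoundError(
            f"no plane with >= {min_inlier_fraction:.0%} inliers "
            f"(best {best_count}/{n_pts})"
        )

    # refine on inliers: centroid + smallest-singular-vector normal
    normal, offset = best
    inliers = points[np.abs(points @ normal - offset) < inlier_threshold]
    centroid = inliers.mean(axis=0)
    _, _, vt = np.linalg.svd(inliers - centroid, full_matrices=False)
    normal = vt[-1]
    if normal @ up < 0:
        normal = -normal
    plane = FloorPlane(normal=normal, offset=float(normal @ centroid))

    if feet is not None:
        feet = np.atleast_2d(np.asarray(feet, dtype=float))
        if np.any(np.abs(plane.distance(feet)) > feet_tolerance):
            raise NoFloorFoundError(
                f"fitted plane is farther than {feet_tolerance} m from a foot prior"
            )
    return plane


# ---------------------------------------------------------------------------
# Body anatomical frame
# ---------------------------------------------------------------------------

@dataclass
class BodyFrame:
    """Anatomical axes: AP (anterior +), ML (subject-left +), vertical (up).

    Pairwise orthogonal, right-handed with ``ap x ml = vertical``.  The
    frontal (lateral) body plane is spanned by the shoulder line and the
    spine; the sagittal plane is perpendicular to it and contains the spine;
    the transverse plane is perpendicular to both, and AP/ML are its
    intersections with the sagittal and frontal planes respectively.
    """

    ap: np.ndarray
    ml: np.ndarray
    vertical: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.ap = _unit(self.ap, "AP axis")
        self.ml = _unit(self.ml, "ML axis")
        self.vertical = _unit(self.vertical, "vertical axis")
        self.origin = np.asarray(self.origin, dtype=float)
        for u, v in ((self.ap, self.ml), (self.ap, self.vertical), (self.ml, self.vertical)):
            if abs(float(u @ v)) > 1e-6:
                raise DegenerateGeometryError("body frame axes not orthogonal")
        if float(np.cross(self.ap, self.ml) @ self.vertical) < 0:
            raise DegenerateGeometryError("body frame is not right-handed")

    def to_dict(self) -> dict:
        return {
            "ap": self.ap.tolist(),
            "ml": self.ml.tolist(),
            "vertical": self.vertical.tolist(),
            "origin": self.origin.tolist(),
        }


def build_body_frame(
    joints: Mapping[str, np.ndarray],
    floor: FloorPlane | None = None,
    vertical: np.ndarray | None = None,
) -> BodyFrame:
    """Anatomical frame from one pose (needs ShouldL/R, SpineB, SpineS).

    The vertical is the floor normal when available (explicit ``vertical``
    takes precedence, then ``floor.normal``), falling back to the spine
    direction (SpineB -> SpineS) for an upright pose; using the true
    vertical keeps trunk lean out of the axes.  ML is the shoulder line
    orthogonalized against the vertical (subject-left positive); AP
    completes a right-handed triad and points anterior.
    """
    for n in ("ShouldL", "ShouldR", "SpineB", "SpineS"):
        if n not in joints or not np.all(np.isfinite(joints[n])):
            raise MissingJointError([n])
    spine = np.asarray(joints["SpineS"], float) - np.asarray(joints["SpineB"], float)
    shoulder = np.asarray(joints["ShouldL"], float) - np.asarray(joints["ShouldR"], float)
    spine_u = _unit(spine, "spine segment")
    if vertical is not None:
        v = _unit(np.asarray(vertical, dtype=float), "vertical")
    elif floor is not None:
        v = floor.normal
    else:
        v = spine_u
    if float(v @ spine_u) < 0:  # orient upward along the body
        v = -v
    ml = shoulder - (shoulder @ v) * v
    ml = _unit(ml, "shoulder line (shoulders coincident or parallel to vertical)")
    ap = np.cross(ml, v)
    return BodyFrame(ap=ap, ml=ml, vertical=v, origin=np.asarray(joints["SpineB"], float))


# ---------------------------------------------------------------------------
# Angles
# ---------------------------------------------------------------------------

def segment_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float | np.ndarray:
    """Angle at vertex ``b`` between rays b->a and b->c, degrees in [0, 180].

    Accepts single points (3,) or stacked trajectories (T, 3); the latter
    returns a (T,) array.
    """
    u = _unit(np.asarray(a, float) - np.asarray(b, float), "segment b->a")
    v = _unit(np.asarray(c, float) - np.asarray(b, float), "segment b->c")
    cosang = np.clip(np.sum(u * v, axis=-1), -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    return float(ang) if np.ndim(ang) == 0 else ang


def trunk_angle(
    spine_s: np.ndarray, spine_b: np.ndarray, vertical: np.ndarray
) -> float | np.ndarray:
    """Unsigned angle between the SpineB->SpineS segment and the vertical."""
    u = _unit(np.asarray(spine_s, float) - np.asarray(spine_b, float), "spine segment")
    v = _unit(np.asarray(vertical, float), "vertical")
    cosang = np.clip(np.sum(u * v, axis=-1), -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    return float(ang) if np.ndim(ang) == 0 else ang


def trunk_angle_sagittal(
    spine_s: np.ndarray, spine_b: np.ndarray, frame: BodyFrame
) -> float | np.ndarray:
    """Signed sagittal-plane inclination of the trunk; anterior lean positive."""
    u = _unit(np.asarray(spine_s, float) - np.asarray(spine_b, float), "spine segment")
    ang = np.degrees(np.arctan2(np.sum(u * frame.ap, axis=-1),
                                np.sum(u * frame.vertical, axis=-1)))
    return float(ang) if np.ndim(ang) == 0 else ang


def head_bend_angles(
    head: np.ndarray,
    spine_s: np.ndarray,
    spine_b: np.ndarray,
    frame: BodyFrame,
) -> tuple[float | np.ndarray, float | np.ndarray]:
    """Signed head-on-spine bending projected on the anatomical planes.

    Returns ``(forward, lateral)`` in degrees: the angle between the
    SpineS->Head segment and the SpineB->SpineS segment after projecting
    both into the sagittal plane (forward/ventral bend positive) and into
    the frontal plane (bend toward the subject's left positive).
    """
    s = _unit(np.asarray(spine_s, float) - np.asarray(spine_b, float), "spine segment")
    h = _unit(np.asarray(head, float) - np.asarray(spine_s, float), "head segment")

    def planar(u, axis):
        return np.arctan2(np.sum(u * axis, axis=-1), np.sum(u * frame.vertical, axis=-1))

    forward = np.degrees(planar(h, frame.ap) - planar(s, frame.ap))
    lateral = np.degrees(planar(h, frame.ml) - planar(s, frame.ml))
    if np.ndim(forward) == 0:
        return float(forward), float(lateral)
    return forward, lateral


def angular_velocity(sig: AngleSignal) -> np.ndarray:
    """Derivative (deg/s) of the cubic-spline interpolant on the same grid."""
    if len(sig) < 4:
        raise InsufficientDataError("need >= 4 samples for spline derivative")
    return CubicSpline(sig.t, sig.values).derivative()(sig.t)


# ---------------------------------------------------------------------------
# Center of mass
# ---------------------------------------------------------------------------

#: The six body segments whose centroids enter the CoM estimate.
COM_SEGMENTS: tuple[tuple[str, str, str], ...] = (
    ("head_trunk_upper", "Head", "SpineS"),
    ("arm_right", "ShouldR", "WristR"),
    ("arm_left", "ShouldL", "WristL"),
    ("trunk", "SpineS", "SpineB"),
    ("leg_right", "HipR", "AnkleR"),
    ("leg_left", "HipL", "AnkleL"),
)

#: Default per-segment weights from standard anthropometric segment-mass
#: tables (head+upper trunk, arms, lower trunk, legs).  Overridable.
DEFAULT_SEGMENT_WEIGHTS: dict[str, float] = {
    "head_trunk_upper": 0.36,
    "arm_right": 0.05,
    "arm_left": 0.05,
    "trunk": 0.22,
    "leg_right": 0.16,
    "leg_left": 0.16,
}


@dataclass
class SegmentWeights:
    """Positive per-segment weights; ``normalize`` makes them a weighted mean.

    With ``normalize=True`` (default) the weights are rescaled to sum to 1,
    the only reading under which the CoM is a scale-correct weighted average
    of segment centroids.  ``normalize=False`` applies the literal
    ``(1/N) * sum(w_i * C_i)`` form instead.
    """

    weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SEGMENT_WEIGHTS)
    )
    normalize: bool = True

    def __post_init__(self) -> None:
        for name, _, _ in COM_SEGMENTS:
            if name not in self.weights:
                raise KeyError(f"missing weight for segment {name!r}")
            if self.weights[name] <= 0:
                raise ValueError(f"weight for {name!r} must be positive")

    def effective(self) -> np.ndarray:
        w = np.array([self.weights[name] for name, _, _ in COM_SEGMENTS], dtype=float)
        if self.normalize:
            return w / w.sum()
        return w / len(w)


def compute_com(
    joints: Mapping[str, np.ndarray], weights: SegmentWeights | None = None
) -> np.ndarray:
    """Body CoM: weighted average of the six segment midpoints.

    Accepts per-frame joints ((3,) points) or trajectories ((T, 3) arrays).
    """
    weights = weights or SegmentWeights()
    missing = [
        j
        for _, p, d in COM_SEGMENTS
        for j in (p, d)
        if j not in joints or not np.all(np.isfinite(joints[j]))
    ]
    if missing:
        raise MissingJointError(sorted(set(missing)))
    w = weights.effective()
    centroids = [
        0.5 * (np.asarray(joints[p], float) + np.asarray(joints[d], float))
        for _, p, d in COM_SEGMENTS
    ]
    return sum(wi * ci for wi, ci in zip(w, centroids))


@dataclass
class ComTrajectory:
    """Per-frame CoM with centered transverse-plane projections in cm."""

    t: np.ndarray
    com3d: np.ndarray
    ap: np.ndarray  # cm, mean-centered
    ml: np.ndarray  # cm, mean-centered

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def crop(self, t0: float, t1: float) -> "ComTrajectory":
        m = (self.t >= t0 - 1e-12) & (self.t <= t1 + 1e-12)
        return ComTrajectory(self.t[m], self.com3d[m], self.ap[m], self.ml[m])


def com_trajectory(
    seq: SkeletonSequence,
    frame: BodyFrame,
    weights: SegmentWeights | None = None,
) -> ComTrajectory:
    """CoM trajectory projected onto the AP/ML axes of a fixed body frame.

    The body frame must be frozen from a reference pose (recomputing it per
    frame would leak trunk motion into the axes).  Projections are centered
    on the trajectory mean and reported in centimeters.
    """
    weights = weights or SegmentWeights()
    needed = sorted({j for _, p, d in COM_SEGMENTS for j in (p, d)})
    seq.require(needed)
    mask = seq.valid_mask(needed)
    joints = {j: seq.joints[j][mask] for j in needed}
    com = compute_com(joints, weights)
    ap = (com @ frame.ap) * 100.0
    ml = (com @ frame.ml) * 100.0
    return ComTrajectory(
        t=seq.t[mask], com3d=com, ap=ap - ap.mean(), ml=ml - ml.mean()
    )
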