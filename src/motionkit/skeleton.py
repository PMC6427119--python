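"""Skeleton data model, I/O and signal preprocessing.

A recording is a time-stamped sequence of 25-joint 3D skeletons in meters,
nominally sampled at 30 Hz by a consumer depth camera (the timestamps carry
jitter).  Scalar signals derived from the joints (joint angles, CoM
components) are resampled onto a uniform 100 Hz grid and low-pass filtered
with a zero-phase second-order Butterworth filter (10 Hz cutoff) before any
feature extraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .errors import (
    InsufficientDataError,
    MissingJointError,
    SkeletonParseError,
    SkeletonValidationError,
    UndefinedLagError,
)

#: The 25 joints of the depth-camera skeleton model.  Naming follows the
#: convention used throughout this package: SpineB (base/pelvis), SpineM
#: (mid), SpineS (shoulder-level spine), plus left/right limb joints.
JOINT_NAMES: tuple[str, ...] = (
    "SpineB", "SpineM", "SpineS", "Neck", "Head",
    "ShouldL", "ElbowL", "WristL", "HandL", "HandTipL", "ThumbL",
    "ShouldR", "ElbowR", "WristR", "HandR", "HandTipR", "ThumbR",
    "HipL", "KneeL", "AnkleL", "FootL",
    "HipR", "KneeR", "AnkleR", "FootR",
)

#: Joints required per task (LA needs hip/knee/ankle; trunk/posture tasks
#: additionally need the spine, head and shoulders; CoM needs the wrists).
REQUIRED_JOINTS: dict[str, tuple[str, ...]] = {
    "la_left": ("HipL", "KneeL", "AnkleL"),
    "la_right": ("HipR", "KneeR", "AnkleR"),
    "ac": ("SpineS", "SpineB"),
    "po": ("SpineS", "SpineB", "Head", "ShouldL", "ShouldR"),
    "ps_com": (
        "SpineS", "SpineB", "Head", "ShouldL", "ShouldR",
        "WristL", "WristR", "HipL", "HipR", "AnkleL", "AnkleR",
    ),
}

DEFAULT_RATE = 30.0           #: nominal device frame rate, Hz
RESAMPLE_RATE = 100.0         #: uniform analysis grid, Hz
FILTER_CUTOFF = 10.0          #: low-pass cutoff, Hz
FILTER_ORDER = 2              #: Butterworth order (single pass)


@dataclass
class SkeletonFrame:
    """One time-stamped skeleton: ``t`` seconds, joints in meters."""

    t: float
    joints: dict[str, np.ndarray]

    def has(self, *names: str) -> bool:
        return all(
            n in self.joints and np.all(np.isfinite(self.joints[n]))
            for n in names
        )


@dataclass
class SkeletonSequence:
    """Ordered skeleton frames stored column-wise for vector math.

    ``t`` is a strictly increasing (T,) array of seconds; ``joints`` maps a
    joint name to a (T, 3) array in meters.  A joint missing in a frame is
    encoded as a NaN row — missing data is flagged, never fabricated.
    """

    t: np.ndarray
    joints: dict[str, np.ndarray]
    nominal_rate: float = DEFAULT_RATE

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.joints = {k: np.asarray(v, dtype=float) for k, v in self.joints.items()}
        self.validate()

    def validate(self) -> None:
        if self.nominal_rate <= 0:
            raise SkeletonValidationError("nominal_rate must be positive")
        if self.t.ndim != 1 or self.t.size == 0:
            raise SkeletonValidationError("timestamp vector empty or not 1-D")
        if not np.all(np.isfinite(self.t)):
            raise SkeletonValidationError("non-finite timestamp")
        if np.any(np.diff(self.t) <= 0):
            i = int(np.flatnonzero(np.diff(self.t) <= 0)[0]) + 1
            raise SkeletonValidationError(
                f"timestamps not strictly increasing at frame {i} (t={self.t[i]!r})"
            )
        for name, arr in self.joints.items():
            if arr.shape != (self.t.size, 3):
                raise SkeletonValidationError(
                    f"joint {name!r} has shape {arr.shape}, expected ({self.t.size}, 3)"
                )

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def frames(self) -> list[SkeletonFrame]:
        return [
            SkeletonFrame(float(self.t[i]), {k: v[i] for k, v in self.joints.items()})
            for i in range(len(self))
        ]

    @classmethod
    def from_frames(
        cls, frames: Sequence[SkeletonFrame], nominal_rate: float = DEFAULT_RATE
    ) -> "SkeletonSequence":
        names = sorted({n for f in frames for n in f.joints})
        t = np.array([f.t for f in frames], dtype=float)
        joints = {
            n: np.array(
                [f.joints.get(n, np.full(3, np.nan)) for f in frames], dtype=float
            )
            for n in names
        }
        return cls(t=t, joints=joints, nominal_rate=nominal_rate)

    def require(self, names: Iterable[str]) -> None:
        """Raise MissingJointError if any joint is entirely absent."""
        missing = [
            n for n in names
            if n not in self.joints or not np.any(np.isfinite(self.joints[n]))
        ]
        if missing:
            raise MissingJointError(missing)

    def valid_mask(self, names: Iterable[str]) -> np.ndarray:
        """Boolean (T,) mask of frames where all named joints are finite."""
        mask = np.ones(len(self), dtype=bool)
        for n in names:
            if n not in self.joints:
                raise MissingJointError([n])
            mask &= np.all(np.isfinite(self.joints[n]), axis=1)
        return mask

    def median_pose(
        self, names: Iterable[str] | None = None, t_max: float | None = None
    ) -> dict[str, np.ndarray]:
        """Per-joint coordinate-wise median position (robust reference pose)."""
        names = list(names) if names is not None else list(self.joints)
        sel = slice(None) if t_max is None else self.t <= t_max
        out = {}
        for n in names:
            arr = self.joints[n][sel]
            arr = arr[np.all(np.isfinite(arr), axis=1)]
            if arr.size == 0:
                raise MissingJointError([n])
            out[n] = np.median(arr, axis=0)
        return out


@dataclass
class AngleSignal:
    """A uniformly sampled scalar angle series in degrees."""

    name: str
    t: np.ndarray
    values: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t.shape != self.values.shape:
            raise SkeletonValidationError("t and values length mismatch")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            if np.max(np.abs(dt - 1.0 / self.rate)) > 1e-9:
                raise SkeletonValidationError("angle signal grid is not uniform")
        if not np.all(np.isfinite(self.values)):
            raise SkeletonValidationError("angle signal contains non-finite values")

    def __len__(self) -> int:
        return int(self.t.size)

    def crop(self, t0: float, t1: float, name: str | None = None) -> "AngleSignal":
        m = (self.t >= t0 - 1e-12) & (self.t <= t1 + 1e-12)
        return AngleSignal(name or self.name, self.t[m], self.values[m], self.rate)


# ---------------------------------------------------------------------------
# I/O — CSV schema: header ``t_s,<Joint>_x,<Joint>_y,<Joint>_z``
# ---------------------------------------------------------------------------

def _csv_columns(names: Sequence[str]) -> list[str]:
    cols = ["t_s"]
    for n in names:
        cols += [f"{n}_x", f"{n}_y", f"{n}_z"]
    return cols


def write_skeleton_csv(seq: SkeletonSequence, path: str | Path) -> None:
    names = [n for n in JOINT_NAMES if n in seq.joints]
    names += [n for n in seq.joints if n not in names]
    data = {"t_s": seq.t}
    for n in names:
        arr = seq.joints[n]
        data[f"{n}_x"], data[f"{n}_y"], data[f"{n}_z"] = arr[:, 0], arr[:, 1], arr[:, 2]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g", lineterminator="\n")


def read_skeleton_csv(path: str | Path, nominal_rate: float = DEFAULT_RATE) -> SkeletonSequence:
    """Read a skeleton CSV (``t_s,<Joint>_x,<Joint>_y,<Joint>_z`` header)."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed file
        raise SkeletonParseError(f"{path}: {exc}") from exc
    if "t_s" not in df.columns:
        raise SkeletonParseError(f"{path}: missing 't_s' column in header")
    names = []
    for col in df.columns:
        if col.endswith("_x"):
            base = col[:-2]
            if f"{base}_y" not in df.columns or f"{base}_z" not in df.columns:
                raise SkeletonParseError(f"{path}: incomplete triplet for joint {base!r}")
            names.append(base)
    if not names:
        raise SkeletonParseError(f"{path}: no joint coordinate columns found")
    for col in df.columns:
        if df[col].dtype == object:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise SkeletonParseError(f"{path}: non-numeric value in {col!r} at line {line}")
    joints = {
        n: np.column_stack([df[f"{n}_x"], df[f"{n}_y"], df[f"{n}_z"]]).astype(float)
        for n in names
    }
    return SkeletonSequence(
        t=df["t_s"].to_numpy(dtype=float), joints=joints, nominal_rate=nominal_rate
    )


def write_skeleton_json(seq: SkeletonSequence, path: str | Path) -> None:
    frames = [
        {
            "t": float(seq.t[i]),
            "joints": {k: [float(x) for x in v[i]] for k, v in seq.joints.items()},
        }
        for i in range(len(seq))
    ]
    Path(path).write_text(
        json.dumps({"rate_hz": seq.nominal_rate, "frames": frames})
    )


def read_skeleton_json(path: str | Path) -> SkeletonSequence:
    try:
        obj = json.loads(Path(path).read_text())
        frames = [
            SkeletonFrame(
                float(f["t"]),
                {k: np.asarray(v, dtype=float) for k, v in f["joints"].items()},
            )
            for f in obj["frames"]
        ]
        rate = float(obj.get("rate_hz", DEFAULT_RATE))
    except (KeyError, ValueError, TypeError, json.JSONDecodeError) as exc:
        raise SkeletonParseError(f"{path}: {exc}") from exc
    return SkeletonSequence.from_frames(frames, nominal_rate=rate)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def design_lowpass(
    cutoff: float = FILTER_CUTOFF,
    rate: float = RESAMPLE_RATE,
    order: int = FILTER_ORDER,
) -> np.ndarray:
    """Second-order sections of the low-pass Butterworth filter.

    The single-pass magnitude response is 1/sqrt(2) at ``cutoff``; the
    pipeline applies it forward-backward (zero phase), which squares the
    magnitude response.
    """
    return sps.butter(order, cutoff, btype="low", fs=rate, output="sos")


def resample_and_filter(
    t: np.ndarray,
    values: np.ndarray,
    target_rate: float = RESAMPLE_RATE,
    cutoff: float = FILTER_CUTOFF,
    order: int = FILTER_ORDER,
    name: str = "signal",
) -> AngleSignal:
    """Resample a jittered scalar series to a uniform grid and low-pass it.

    A cubic spline is fit on the original (jittered) timestamps and
    evaluated on a uniform ``target_rate`` grid spanning the input; the
    Butterworth filter is applied with ``filtfilt`` (zero phase) so cycle
    timing is not lagged.
    """
    t = np.asarray(t, dtype=float)
    values = np.asarray(values, dtype=float)
    if t.size < 4:
        raise InsufficientDataError(f"{name}: need >= 4 samples, got {t.size}")
    if t[-1] - t[0] < 2.0 / cutoff:
        raise InsufficientDataError(
            f"{name}: duration {t[-1] - t[0]:.3f} s < {2.0 / cutoff:.3f} s minimum"
        )
    spline = CubicSpline(t, values)
    n = int(np.floor((t[-1] - t[0]) * target_rate)) + 1
    grid = t[0] + np.arange(n) / target_rate
    resampled = spline(grid)
    sos = design_lowpass(cutoff, target_rate, order)
    filtered = sps.sosfiltfilt(sos, resampled)
    return AngleSignal(name=name, t=grid, values=filtered, rate=target_rate)


def series_from_sequence(
    seq: SkeletonSequence,
    joints: Sequence[str],
    func: Callable[..., np.ndarray],
    max_dropped_fraction: float = 0.10,
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate ``func(*joint_arrays)`` per frame, dropping invalid frames.

    Frames where any required joint is missing (NaN) are dropped; if more
    than ``max_dropped_fraction`` of frames are dropped the recording is
    considered unusable and a hard error is raised.
    """
    seq.require(joints)
    mask = seq.valid_mask(joints)
    dropped = 1.0 - mask.mean()
    if dropped > max_dropped_fraction:
        raise SkeletonValidationError(
            f"{dropped:.0%} of frames miss a required joint "
            f"(limit {max_dropped_fraction:.0%})"
        )
    arrays = [seq.joints[j][mask] for j in joints]
    return seq.t[mask], np.asarray(func(*arrays), dtype=float)


def synchronize_by_crosscorr(a: np.ndarray, b: np.ndarray, rate: float) -> float:
    """Time shift of ``b`` relative to ``a`` maximizing their cross-correlation.

    Both series must share the uniform ``rate``.  Signals are mean-removed
    first; a positive lag means ``b`` is delayed with respect to ``a``
    (``b[n] ~ a[n - lag*rate]``).  Ties in the correlation peak are broken
    toward the smallest absolute lag.
    """
    a = np.asarray(a, dtype=float) - np.mean(a)
    b = np.asarray(b, dtype=float) - np.mean(b)
    if min(a.size, b.size) < rate:  # < 1 s overlap
        raise InsufficientDataError("need at least 1 s of overlapping signal")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedLagError("flat (zero-variance) input: lag undefined")
    c = sps.correlate(b, a, mode="full")
    lags = sps.correlation_lags(b.size, a.size, mode="full")
    peak = np.max(c)
    # tie-break toward smallest |lag| among near-exact ties
    candidates = lags[c >= peak * (1 - 1e-12)] if peak > 0 else lags[c == peak]
    lag = int(candidates[np.argmin(np.abs(candidates))])
    return lag / rate
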