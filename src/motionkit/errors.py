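"""Exception hierarchy for motionkit.

Every error raised on bad scientific input derives from MotionKitError so
callers can distinguish pipeline failures from programming errors.
"""


class MotionKitError(Exception):
    """Base class for all motionkit errors."""


class SkeletonParseError(MotionKitError):
    """Malformed skeleton file (bad header, wrong column count, bad row)."""


class SkeletonValidationError(MotionKitError):
    """Skeleton data violates an invariant (e.g. non-monotone timestamps)."""


class MissingJointError(MotionKitError):
    """A joint required by the requested computation is absent."""

    def __init__(self, joints):
        self.joints = tuple(joints)
        super().__init__(f"required joint(s) missing: {', '.join(self.joints)}")


class InsufficientDataError(MotionKitError):
    """Series too short / too few samples for the requested operation."""


class DegenerateGeometryError(MotionKitError):
    """Zero-length segment, coincident points, collinear plane input, ..."""


class NoFloorFoundError(MotionKitError):
    """RANSAC could not find a floor plane meeting the inlier/prior checks."""


class UndefinedLagError(MotionKitError):
    """Cross-correlation lag undefined (flat input)."""


class InsufficientMovementError(MotionKitError):
    """No movement cycle detected where at least one is required."""


class IncompleteSitToStandError(InsufficientMovementError):
    """No trunk-bending cycle found in a sit-to-stand recording."""


class UndefinedStatisticError(MotionKitError):
    """A statistic is undefined on this input (zero variance, zero mean...)."""
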