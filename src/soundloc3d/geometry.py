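"""Rigid-body poses, head-center calibration, and coordinate frames.

All tracked elements (loudspeaker, head, hand, gaze) live in the
motion-capture world frame; analysis happens in a head-centered frame whose
origin is the midpoint of the two ears and whose forward axis is the head's
straight-ahead direction at sound-delivery onset.

Axis convention (right-handed): x = right, y = forward (straight ahead),
z = up.  Azimuth = atan2(x, y) in degrees, positive rightward, 0 straight
ahead, range (-180, 180].  Elevation = atan2(z, hypot(x, y)), positive up.
Depth is the Euclidean distance from the head center, reported in cm.
Internal computation uses meters and radians throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Pose",
    "HeadCalibration",
    "SphericalCoord",
    "TargetPosition",
    "TARGET_GRID",
    "calibrate_head_center",
    "to_head_frame",
    "from_head_frame",
    "cartesian_to_spherical",
    "spherical_to_cartesian",
    "forward_direction",
    "facing_azimuth_deg",
]

_QUAT_NORM_TOL = 1e-6
M_TO_CM = 100.0


@dataclass(frozen=True)
class Pose:
    """Timestamped rigid-body state: position (m) + unit quaternion (x,y,z,w)."""

    t: float
    position: np.ndarray
    orientation: np.ndarray  # scalar-last, scipy convention

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        object.__setattr__(self, "orientation", np.asarray(self.orientation, dtype=float))
        if not np.isfinite(self.t) or self.t < 0:
            raise ValueError(f"pose time must be finite and non-negative, got {self.t}")
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("pose position must be a finite 3-vector")
        q = self.orientation
        if q.shape != (4,) or abs(np.linalg.norm(q) - 1.0) > _QUAT_NORM_TOL:
            raise ValueError("pose orientation must be a unit quaternion (x, y, z, w)")

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_quat(self.orientation)


@dataclass(frozen=True)
class HeadCalibration:
    """Per-participant ear positions and their midpoint (the head center), meters."""

    left_ear: np.ndarray
    right_ear: np.ndarray
    head_center: np.ndarray


@dataclass(frozen=True)
class SphericalCoord:
    """Head-centered polar coordinate: azimuth/elevation in degrees, depth in cm.

    ``degenerate`` marks a zero-depth point, where direction is undefined and
    both angles are reported as 0.
    """

    azimuth: float
    elevation: float
    depth: float
    degenerate: bool = False


#: The experiment's target grid: 4 azimuths x 3 depths at ear level.
TARGET_AZIMUTHS_DEG = (-150.0, -30.0, 30.0, 150.0)
TARGET_DEPTHS_CM = (35.0, 55.0, 75.0)
DEPTH_LABELS = {35.0: "near", 55.0: "middle", 75.0: "far"}


@dataclass(frozen=True)
class TargetPosition:
    """One of the 12 predetermined head-centered loudspeaker positions."""

    azimuth: float
    depth: float
    elevation: float = 0.0

    def __post_init__(self):
        if self.azimuth not in TARGET_AZIMUTHS_DEG:
            raise ValueError(f"target azimuth must be one of {TARGET_AZIMUTHS_DEG}")
        if self.depth not in TARGET_DEPTHS_CM:
            raise ValueError(f"target depth must be one of {TARGET_DEPTHS_CM}")
        if self.elevation != 0.0:
            raise ValueError("all targets lie at ear level (elevation 0)")

    @property
    def sector(self) -> str:
        return "front" if abs(self.azimuth) < 90.0 else "back"

    @property
    def distance(self) -> str:
        return DEPTH_LABELS[self.depth]

    def cartesian_m(self) -> np.ndarray:
        return spherical_to_cartesian(SphericalCoord(self.azimuth, self.elevation, self.depth))


TARGET_GRID: tuple[TargetPosition, ...] = tuple(
    TargetPosition(az, d) for az in TARGET_AZIMUTHS_DEG for d in TARGET_DEPTHS_CM
)


def calibrate_head_center(left_ear, right_ear) -> HeadCalibration:
    """Head-center calibration: the midpoint of the two tracked ear positions."""
    left = np.asarray(left_ear, dtype=float)
    right = np.asarray(right_ear, dtype=float)
    if left.shape != (3,) or right.shape != (3,):
        raise ValueError("ear positions must be 3-vectors")
    if not (np.all(np.isfinite(left)) and np.all(np.isfinite(right))):
        raise ValueError("ear positions must be finite")
    return HeadCalibration(left_ear=left, right_ear=right, head_center=(left + right) / 2.0)


def _head_center_world(reference_head: Pose, head_center_offset) -> np.ndarray:
    offset = np.asarray(head_center_offset, dtype=float)
    return reference_head.position + reference_head.rotation.apply(offset)


def to_head_frame(point_world, reference_head: Pose, head_center_offset=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Express a world-frame point in the head-centered frame of ``reference_head``.

    ``reference_head`` is the straight-ahead-aligned head pose captured at
    sound-delivery onset; ``head_center_offset`` is the calibrated translation
    (head-local coordinates, m) from the tracked rigid-body origin to the
    midpoint of the ears.
    """
    p = np.asarray(point_world, dtype=float)
    center = _head_center_world(reference_head, head_center_offset)
    return reference_head.rotation.inv().apply(p - center)


def from_head_frame(point_head, reference_head: Pose, head_center_offset=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Inverse of :func:`to_head_frame`."""
    p = np.asarray(point_head, dtype=float)
    center = _head_center_world(reference_head, head_center_offset)
    return reference_head.rotation.apply(p) + center


def cartesian_to_spherical(point_head) -> SphericalCoord:
    """Convert a head-frame point (m) to azimuth/elevation (deg) and depth (cm)."""
    p = np.asarray(point_head, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("point must be finite")
    r = float(np.linalg.norm(p))
    if r == 0.0:
        return SphericalCoord(0.0, 0.0, 0.0, degenerate=True)
    azimuth = np.degrees(np.arctan2(p[0], p[1]))
    if azimuth <= -180.0:  # map -180 to +180 so the range is (-180, 180]
        azimuth += 360.0
    elevation = np.degrees(np.arctan2(p[2], np.hypot(p[0], p[1])))
    return SphericalCoord(float(azimuth), float(elevation), r * M_TO_CM)


def spherical_to_cartesian(coord: SphericalCoord) -> np.ndarray:
    """Inverse of :func:`cartesian_to_spherical`; returns meters."""
    az = np.radians(coord.azimuth)
    el = np.radians(coord.elevation)
    r = coord.depth / M_TO_CM
    return np.array(
        [r * np.cos(el) * np.sin(az), r * np.cos(el) * np.cos(az), r * np.sin(el)]
    )


def forward_direction(rotation: Rotation) -> np.ndarray:
    """World-frame unit vector along the head's straight-ahead (+y) axis."""
    return rotation.apply(np.array([0.0, 1.0, 0.0]))


def facing_azimuth_deg(head_quat_xyzw, reference_head: Pose) -> float:
    """Azimuth (deg) of the head's facing direction in the reference head frame."""
    fwd_world = forward_direction(Rotation.from_quat(np.asarray(head_quat_xyzw, dtype=float)))
    fwd_ref = reference_head.rotation.inv().apply(fwd_world)
    az = np.degrees(np.arctan2(fwd_ref[0], fwd_ref[1]))
    if az <= -180.0:
        az += 360.0
    return float(az)
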