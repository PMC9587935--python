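"""Sound-delivery gating: offline re-implementation of the trial controller.

Sound is delivered only when three criteria hold at once: the loudspeaker
sits within a tolerance sphere (2.5 cm radius) of its predetermined
head-centered position, and the participant's head and eyes are aligned
straight ahead within angular tolerances.  The first passing sample defines
the delivery onset, which is the kinematic time reference (t = 0) for
everything downstream.

The head/eye angular tolerances are a configuration choice (the original
controller's values are not public); defaults are 5 degrees each.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GatingCriteria", "GatingDecision", "check_delivery", "find_delivery_onset", "NoDeliveryError"]

_UNIT_TOL = 1e-6
M_TO_CM = 100.0


class NoDeliveryError(RuntimeError):
    """Raised when the delivery criteria are never concurrently met."""


@dataclass(frozen=True)
class GatingCriteria:
    placement_tolerance_cm: float = 2.5
    head_tolerance_deg: float = 5.0
    eye_tolerance_deg: float = 5.0

    def __post_init__(self):
        for name in ("placement_tolerance_cm", "head_tolerance_deg", "eye_tolerance_deg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class GatingDecision:
    deliver: bool
    failed_criteria: frozenset = field(default_factory=frozenset)
    placement_error_3d_cm: float = np.nan
    head_deviation_deg: float = np.nan
    eye_deviation_deg: float = np.nan


def _angle_from_deg(direction, reference) -> float:
    d = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(d) - 1.0) > _UNIT_TOL:
        raise ValueError("direction vectors must be unit-norm")
    cosang = np.clip(np.dot(d, reference), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def check_delivery(
    speaker_pos_m,
    target_pos_m,
    head_dir,
    eye_dir,
    criteria: GatingCriteria = GatingCriteria(),
    straight_ahead=(0.0, 1.0, 0.0),
) -> GatingDecision:
    """Evaluate the three delivery criteria at one instant.

    Positions in meters (head-centered), directions unit-norm.  Boundaries are
    inclusive: a placement error exactly at the tolerance passes (the
    tolerance sphere is a closed ball).
    """
    speaker = np.asarray(speaker_pos_m, dtype=float)
    target = np.asarray(target_pos_m, dtype=float)
    ref = np.asarray(straight_ahead, dtype=float)
    ref = ref / np.linalg.norm(ref)

    placement_cm = float(np.linalg.norm(speaker - target)) * M_TO_CM
    head_dev = _angle_from_deg(head_dir, ref)
    eye_dev = _angle_from_deg(eye_dir, ref)

    failed = set()
    if placement_cm > criteria.placement_tolerance_cm:
        failed.add("placement")
    if head_dev > criteria.head_tolerance_deg:
        failed.add("head")
    if eye_dev > criteria.eye_tolerance_deg:
        failed.add("eye")
    return GatingDecision(
        deliver=not failed,
        failed_criteria=frozenset(failed),
        placement_error_3d_cm=placement_cm,
        head_deviation_deg=head_dev,
        eye_deviation_deg=eye_dev,
    )


def find_delivery_onset(
    t,
    speaker_pos_m,
    target_pos_m,
    head_dirs,
    eye_dirs,
    criteria: GatingCriteria = GatingCriteria(),
    straight_ahead=(0.0, 1.0, 0.0),
) -> float:
    """Earliest sample time at which all delivery criteria pass.

    ``speaker_pos_m``, ``head_dirs`` and ``eye_dirs`` are (n, 3) arrays on the
    sampling grid ``t``; ``target_pos_m`` is the trial's predetermined
    position, either fixed (3,) or tracked per sample (n, 3).  Triggers on
    the first passing sample (no sustain requirement).
    """
    t = np.asarray(t, dtype=float)
    speaker = np.atleast_2d(np.asarray(speaker_pos_m, dtype=float))
    target = np.asarray(target_pos_m, dtype=float)
    heads = np.atleast_2d(np.asarray(head_dirs, dtype=float))
    eyes = np.atleast_2d(np.asarray(eye_dirs, dtype=float))
    ref = np.asarray(straight_ahead, dtype=float)
    ref = ref / np.linalg.norm(ref)
    if np.any(np.abs(np.linalg.norm(heads, axis=1) - 1.0) > _UNIT_TOL) or np.any(
        np.abs(np.linalg.norm(eyes, axis=1) - 1.0) > _UNIT_TOL
    ):
        raise ValueError("direction vectors must be unit-norm")

    placement_cm = np.linalg.norm(speaker - target, axis=1) * M_TO_CM
    head_dev = np.degrees(np.arccos(np.clip(heads @ ref, -1.0, 1.0)))
    eye_dev = np.degrees(np.arccos(np.clip(eyes @ ref, -1.0, 1.0)))
    ok = (
        (placement_cm <= criteria.placement_tolerance_cm)
        & (head_dev <= criteria.head_tolerance_deg)
        & (eye_dev <= criteria.eye_tolerance_deg)
    )
    idx = np.flatnonzero(ok)
    if len(idx) == 0:
        raise NoDeliveryError("delivery criteria never concurrently met in this trial")
    return float(t[idx[0]])
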