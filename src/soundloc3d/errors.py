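"""Localization-error statistics.

Per-dimension errors compare the hand response with the speaker position at
delivery, both in the head-centered frame: azimuth and elevation errors in
degrees (azimuth as a circular difference wrapped to (-180, 180]), depth
errors in cm.  The absolute error measures accuracy; the variable error — the
SD of repeated responses at the same target, averaged across targets —
measures precision.

The composite 3D error combines the mean per-trial 3D response-to-target
distance C_bar with the mean per-position response dispersion s_bar:

    error_3d = sqrt(C_bar**2 + s_bar**2)

C_i is the Euclidean norm (cm) of response_i - target_i, averaged over all
accepted trials irrespective of sound position.  The per-position dispersion
of the 3D responses is, by default, the RMS distance from the position's mean
response, sqrt(var_x + var_y + var_z) with n-1 denominators ("rms" rule); a
per-axis-SD average ("axis_mean") is available as a config switch since the
one-number-per-position reading is an interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import cartesian_to_spherical

__all__ = [
    "ResponseRecord",
    "ErrorSummary",
    "dimension_errors",
    "wrap_angle_deg",
    "variable_error",
    "error_3d",
    "placement_accuracy",
    "error_table",
]

M_TO_CM = 100.0


@dataclass(frozen=True)
class ResponseRecord:
    """One accepted trial's head-frame response and target (m) plus design labels."""

    response: np.ndarray
    target: np.ndarray
    condition: str  # 'static' | 'active'
    sector: str  # 'front' | 'back'
    distance: str  # 'near' | 'middle' | 'far'
    position_id: object = None  # identifies the target position for dispersion grouping


@dataclass(frozen=True)
class ErrorSummary:
    C_bar: float  # mean per-trial 3D norm, cm
    s_bar: float  # mean per-position 3D response dispersion, cm
    error_3d: float
    n_trials: int
    n_positions: int
    skipped_positions: int = 0


def wrap_angle_deg(angle: float) -> float:
    """Wrap an angular difference to (-180, 180]."""
    wrapped = (angle + 180.0) % 360.0 - 180.0
    if wrapped == -180.0:
        wrapped = 180.0
    return wrapped


def dimension_errors(record: ResponseRecord) -> dict:
    """Signed and absolute errors per dimension for one trial.

    Azimuth error is the circular difference response - target; depth error is
    in cm.  A zero-depth response or target is degenerate: flagged and meant
    to be excluded from aggregates.
    """
    resp = cartesian_to_spherical(record.response)
    targ = cartesian_to_spherical(record.target)
    if resp.degenerate or targ.degenerate:
        return {"degenerate": True}
    az_signed = wrap_angle_deg(resp.azimuth - targ.azimuth)
    el_signed = resp.elevation - targ.elevation
    depth_signed = resp.depth - targ.depth
    return {
        "degenerate": False,
        "azimuth_signed": az_signed,
        "azimuth_abs": abs(az_signed),
        "elevation_signed": el_signed,
        "elevation_abs": abs(el_signed),
        "depth_signed": depth_signed,
        "depth_abs": abs(depth_signed),
    }


def variable_error(values_by_position: dict, min_trials: int = 2) -> tuple[float, int]:
    """Mean across positions of the per-position response SD (n-1 denominator).

    ``values_by_position`` maps position id -> 1-D array of one dimension's
    response values (deg or cm).  Positions with fewer than ``min_trials``
    responses are skipped.  Returns (participant value, n positions skipped);
    NaN when no position qualifies.
    """
    sds, skipped = [], 0
    for vals in values_by_position.values():
        v = np.asarray(vals, dtype=float)
        if v.size < min_trials:
            skipped += 1
            continue
        sds.append(np.std(v, ddof=1))
    if not sds:
        return float("nan"), skipped
    return float(np.mean(sds)), skipped


def _dispersion_3d(responses_cm: np.ndarray, rule: str) -> float:
    var = np.var(responses_cm, axis=0, ddof=1)  # per-axis, n-1
    if rule == "rms":
        return float(np.sqrt(var.sum()))
    if rule == "axis_mean":
        return float(np.mean(np.sqrt(var)))
    raise ValueError(f"unknown dispersion rule {rule!r} (use 'rms' or 'axis_mean')")


def error_3d(records: list[ResponseRecord], dispersion: str = "rms", min_trials: int = 2) -> ErrorSummary:
    """Composite 3D error for one participant x condition.

    C_bar pools every accepted trial; s_bar averages the per-position 3D
    dispersion over positions with at least ``min_trials`` responses.
    """
    if not records:
        raise ValueError("no accepted trials: cannot compute 3D error")
    C = [np.linalg.norm(r.response - r.target) * M_TO_CM for r in records]
    C_bar = float(np.mean(C))

    by_pos: dict = {}
    for r in records:
        by_pos.setdefault(r.position_id, []).append(np.asarray(r.response, float) * M_TO_CM)
    dispersions, skipped = [], 0
    for resp in by_pos.values():
        arr = np.vstack(resp)
        if arr.shape[0] < min_trials:
            skipped += 1
            continue
        dispersions.append(_dispersion_3d(arr, dispersion))
    s_bar = float(np.mean(dispersions)) if dispersions else 0.0
    return ErrorSummary(
        C_bar=C_bar,
        s_bar=s_bar,
        error_3d=float(np.hypot(C_bar, s_bar)),
        n_trials=len(records),
        n_positions=len(dispersions),
        skipped_positions=skipped,
    )


def placement_accuracy(predetermined_m: np.ndarray, actual_m: np.ndarray) -> dict:
    """Speaker-placement accuracy across stimulations, in cm.

    Per-axis mean absolute difference between actual and predetermined
    positions, plus the mean 3D Euclidean norm.
    """
    pre = np.atleast_2d(np.asarray(predetermined_m, dtype=float))
    act = np.atleast_2d(np.asarray(actual_m, dtype=float))
    if pre.shape != act.shape:
        raise ValueError("predetermined and actual position arrays must align")
    diff_cm = (act - pre) * M_TO_CM
    per_axis = np.mean(np.abs(diff_cm), axis=0)
    return {
        "x_cm": float(per_axis[0]),
        "y_cm": float(per_axis[1]),
        "z_cm": float(per_axis[2]),
        "norm_3d_cm": float(np.mean(np.linalg.norm(diff_cm, axis=1))),
        "n": pre.shape[0],
    }


def error_table(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy per-participant x condition x sector error statistics.

    ``df`` carries one accepted trial per row with columns participant,
    condition, sector, distance, position_id, the signed/absolute dimension
    errors from :func:`dimension_errors`, and azimuth/elevation/depth response
    values (for variable errors).  Depth statistics are additionally split by
    distance.  Angles in degrees, depths in cm.
    """
    rows = []
    for (pid, cond, sector), g in df.groupby(["participant", "condition", "sector"], sort=True):
        row = {"participant": pid, "condition": cond, "sector": sector}
        for dim in ("azimuth", "elevation"):
            row[f"{dim}_abs_error"] = g[f"{dim}_abs"].mean()
            row[f"{dim}_signed_error"] = g[f"{dim}_signed"].mean()
            by_pos = {k: v[f"{dim}_response"].to_numpy() for k, v in g.groupby("position_id")}
            row[f"{dim}_variable_error"], _ = variable_error(by_pos)
        rows.append(row)
    out = pd.DataFrame(rows)

    depth_rows = []
    for (pid, cond, sector, dist), g in df.groupby(
        ["participant", "condition", "sector", "distance"], sort=True
    ):
        by_pos = {k: v["depth_response"].to_numpy() for k, v in g.groupby("position_id")}
        var_err, _ = variable_error(by_pos)
        depth_rows.append(
            {
                "participant": pid,
                "condition": cond,
                "sector": sector,
                "distance": dist,
                "depth_abs_error": g["depth_abs"].mean(),
                "depth_signed_error": g["depth_signed"].mean(),
                "depth_response_mean": g["depth_response"].mean(),
                "depth_variable_error": var_err,
            }
        )
    return out, pd.DataFrame(depth_rows)
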