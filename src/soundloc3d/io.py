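"""File schemas and validated I/O.

Track files are long-format CSV with one row per sample:

    participant, trial, body, t, x, y, z, qw, qx, qy, qz

``body`` is one of head / eye / hand / speaker; positions in meters, times in
seconds, quaternions scalar-first (``qw``) and empty for point-only bodies.
A ``#``-prefixed header comment documents the units.  Trial tables carry one
row per trial with the design labels and the predetermined/actual speaker and
response positions in head-centered meters.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_tracks", "read_tracks", "write_trials", "read_trials", "SchemaError"]

TRACK_COLUMNS = ["participant", "trial", "body", "t", "x", "y", "z", "qw", "qx", "qy", "qz"]
BODIES = {"head", "eye", "hand", "speaker"}
TRIAL_REQUIRED = [
    "participant", "trial", "block", "condition", "position_id",
    "target_azimuth", "target_depth", "sector", "distance",
    "pre_x", "pre_y", "pre_z", "act_x", "act_y", "act_z",
]
_TRACK_HEADER = "# soundloc3d tracks: positions in meters, t in seconds, quaternions scalar-first (qw)\n"
_TRIAL_HEADER = "# soundloc3d trials: head-centered positions in meters, angles in degrees, depths in cm\n"
_QUAT_TOL = 1e-6


class SchemaError(ValueError):
    """A file does not conform to the documented schema."""


def write_tracks(tracks: pd.DataFrame, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_TRACK_HEADER)
        tracks[TRACK_COLUMNS].to_csv(fh, index=False)


def read_tracks(path) -> pd.DataFrame:
    """Read and validate a track CSV; raises :class:`SchemaError` naming offenders."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    bad_bodies = set(df["body"].unique()) - BODIES
    if bad_bodies:
        raise SchemaError(f"{path}: unknown body labels {sorted(bad_bodies)}")
    for col in ("t", "x", "y", "z"):
        bad = df.index[~np.isfinite(df[col].to_numpy(dtype=float))]
        if len(bad):
            raise SchemaError(f"{path}: non-finite value in column {col!r}, row {int(bad[0]) + 2}")
    quat = df[["qx", "qy", "qz", "qw"]].to_numpy(dtype=float)
    has_quat = ~np.isnan(quat).any(axis=1)
    norms = np.linalg.norm(quat[has_quat], axis=1)
    off = np.flatnonzero(np.abs(norms - 1.0) > _QUAT_TOL)
    if len(off):
        row = int(np.flatnonzero(has_quat)[off[0]]) + 2
        raise SchemaError(f"{path}: non-unit quaternion at row {row} (norm {norms[off[0]]:.6f})")
    head_rows = df["body"] == "head"
    if head_rows.any() and df.loc[head_rows, "qw"].isna().any():
        bad = df.index[head_rows & df["qw"].isna()][0]
        raise SchemaError(f"{path}: head sample without orientation at row {int(bad) + 2}")
    return df


def write_trials(trials: pd.DataFrame, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_TRIAL_HEADER)
        trials.to_csv(fh, index=False)


def read_trials(path, tracks: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read and validate a trial table; cross-checks track coverage when given."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in TRIAL_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    bad_cond = set(df["condition"].unique()) - {"static", "active"}
    if bad_cond:
        raise SchemaError(f"{path}: unknown conditions {sorted(bad_cond)}")
    if tracks is not None:
        have = set(map(tuple, tracks[["participant", "trial"]].drop_duplicates().to_numpy()))
        want = set(map(tuple, df[["participant", "trial"]].to_numpy()))
        orphans = sorted(want - have)
        if orphans:
            raise SchemaError(f"{path}: trials without tracks: {orphans[:10]}")
    return df
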