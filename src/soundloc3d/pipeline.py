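"""End-to-end analysis: gating -> re-referencing -> kinematics -> rejection
-> localization errors -> statistics, with manifest bookkeeping.

Per trial, the delivery onset is located offline from the tracks (speaker
within the placement tolerance of the predetermined head-centered position,
head and gaze straight ahead), the head pose at that sample becomes the
reference frame and t = 0, and all tracked points are re-expressed in
head-centered coordinates.  Head and hand tracks are filtered and segmented;
non-compliant trials (anticipatory hand movements, head movements during
static listening) are rejected.  Error statistics aggregate trial ->
participant -> group, never pooling trials across participants.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.transform import Rotation

from . import errors as err
from . import gating, kinematics, stats
from .geometry import Pose, cartesian_to_spherical, to_head_frame, from_head_frame
from .simulate import HEAD_CENTER_OFFSET, GeneratorConfig, generate_experiment

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "analyze_tracks", "response_table"]

log = logging.getLogger("soundloc3d")

_RESPONSE_HOLD_S = 0.2  # response = mean hand position over the final window


@dataclass
class RunConfig:
    """One reproducible run: generator or input paths plus stage settings."""

    seed: int = 0
    out_dir: str | None = None
    generator: GeneratorConfig | None = None
    trials_path: str | None = None
    tracks_path: str | None = None
    gating_criteria: gating.GatingCriteria = field(default_factory=gating.GatingCriteria)
    kin_cutoff_hz: float = 50.0
    kin_threshold_mm_s: float = 80.0
    kin_min_duration_ms: float = 50.0
    sound_window_s: tuple = (0.0, 3.0)
    dispersion: str = "rms"  # 3D per-position dispersion rule: 'rms' | 'axis_mean'
    head_center_offset: tuple = HEAD_CENTER_OFFSET
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load a flat key-value config file (dotted keys select sub-configs)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs, gen_kwargs, gate_kwargs = {}, {}, {}
        for key, value in raw.items():
            if key.startswith("generator."):
                gen_kwargs[key.split(".", 1)[1]] = value
            elif key == "gating.placement_tolerance_cm":
                gate_kwargs["placement_tolerance_cm"] = value
            elif key == "gating.head_tolerance_deg":
                gate_kwargs["head_tolerance_deg"] = value
            elif key == "gating.eye_tolerance_deg":
                gate_kwargs["eye_tolerance_deg"] = value
            elif key.startswith("kin."):
                kwargs[{"cutoff_hz": "kin_cutoff_hz",
                        "threshold_mm_s": "kin_threshold_mm_s",
                        "min_duration_ms": "kin_min_duration_ms",
                        "sound_window_s": "sound_window_s"}[key.split(".", 1)[1]]] = value
            elif key.startswith("errors."):
                kwargs[key.split(".", 1)[1]] = value
            else:
                kwargs[key] = value
        if gen_kwargs:
            kwargs["generator"] = GeneratorConfig(**gen_kwargs)
        if gate_kwargs:
            kwargs["gating_criteria"] = gating.GatingCriteria(**gate_kwargs)
        if "sound_window_s" in kwargs:
            kwargs["sound_window_s"] = tuple(kwargs["sound_window_s"])
        return cls(**kwargs)


@dataclass
class PipelineResult:
    trial_results: pd.DataFrame
    error_table: pd.DataFrame
    depth_error_table: pd.DataFrame
    summary_3d: pd.DataFrame
    head_movements: pd.DataFrame
    placement: dict
    stat_results: list
    stats_table: pd.DataFrame
    report_text: str
    manifest: dict


def _trial_frames(tracks: pd.DataFrame):
    for key, group in tracks.groupby(["participant", "trial"], sort=True):
        yield key, {body: g.sort_values("t") for body, g in group.groupby("body")}


def analyze_tracks(trials: pd.DataFrame, tracks: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Per-trial kinematic + response analysis; one row per input trial.

    Rows carry the compliance decision, head-movement metrics, the response
    and target in head-centered coordinates, and per-dimension errors (for
    accepted trials).  Trials whose delivery criteria never pass are marked
    rejected with reason ``no_delivery``.
    """
    trial_meta = trials.set_index(["participant", "trial"])
    rows = []
    for (participant, trial), bodies in _trial_frames(tracks):
        meta = trial_meta.loc[(participant, trial)]
        row = {
            "participant": participant,
            "trial": trial,
            "condition": meta["condition"],
            "sector": meta["sector"],
            "distance": meta["distance"],
            "position_id": meta["position_id"],
        }
        try:
            row.update(_analyze_one(meta, bodies, cfg))
        except gating.NoDeliveryError:
            row.update({"accepted": False, "reason": "no_delivery"})
        rows.append(row)
    return pd.DataFrame(rows)


def _analyze_one(meta, bodies, cfg: RunConfig) -> dict:
    head = bodies["head"]
    hand = bodies["hand"]
    speaker = bodies["speaker"]
    eye = bodies.get("eye")

    t = head["t"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(t)))
    head_pos = head[["x", "y", "z"]].to_numpy()
    head_quat = head[["qx", "qy", "qz", "qw"]].to_numpy()
    hand_pos = hand[["x", "y", "z"]].to_numpy()
    speaker_pos = speaker[["x", "y", "z"]].to_numpy()

    # predetermined target in world coordinates, tracked per sample with the
    # head pose (the controller re-expressed it in head-centered coordinates
    # continuously)
    pre_head = meta[["pre_x", "pre_y", "pre_z"]].to_numpy(dtype=float)
    rot = Rotation.from_quat(head_quat)
    head_center = head_pos + rot.apply(np.asarray(cfg.head_center_offset, dtype=float))
    target_world = head_center + rot.apply(pre_head)
    head_dirs = rot.apply(np.array([0.0, 1.0, 0.0]))
    if eye is not None:
        te = eye["t"].to_numpy()
        eye_xyz = eye[["x", "y", "z"]].to_numpy()
        eye_dirs = np.column_stack([np.interp(t, te, eye_xyz[:, i]) for i in range(3)])
        eye_dirs /= np.linalg.norm(eye_dirs, axis=1, keepdims=True)
    else:
        eye_dirs = head_dirs  # no gaze track: head alignment stands in

    straight = head_dirs[0]  # recorded straight-ahead reference at trial start
    t0 = gating.find_delivery_onset(
        t, speaker_pos, target_world, head_dirs, eye_dirs, cfg.gating_criteria, straight
    )
    i0 = int(np.searchsorted(t, t0))
    ref_pose = Pose(t0, head_pos[i0], head_quat[i0] / np.linalg.norm(head_quat[i0]))
    t_rel = t - t0

    # kinematics on filtered world-frame positions (speed is frame-invariant)
    head_filt = kinematics.lowpass_filter(head_pos, fs, cfg.kin_cutoff_hz)
    hand_filt = kinematics.lowpass_filter(hand_pos, fs, cfg.kin_cutoff_hz)
    head_speed = kinematics.velocity(head_filt, fs, t0=t_rel[0])
    hand_speed = kinematics.velocity(hand_filt, fs, t0=t_rel[0])
    min_dur = cfg.kin_min_duration_ms / 1000.0
    head_segs = kinematics.segment_movements(head_speed, cfg.kin_threshold_mm_s, min_dur)
    hand_segs = kinematics.segment_movements(hand_speed, cfg.kin_threshold_mm_s, min_dur)

    fwd_ref = ref_pose.rotation.inv().apply(head_dirs)
    facing_az = np.degrees(np.arctan2(fwd_ref[:, 0], fwd_ref[:, 1]))
    metrics = kinematics.head_movement_metrics(head_segs, (t_rel, facing_az), cfg.sound_window_s)

    compliance = kinematics.check_compliance(
        (meta.name if hasattr(meta, "name") else None),
        meta["condition"], head_segs, hand_segs, cfg.sound_window_s,
    )

    # response: hand held at the pointed position over the final window
    hold = t_rel >= t_rel[-1] - _RESPONSE_HOLD_S
    resp_world = hand_pos[hold].mean(axis=0)
    resp_head = to_head_frame(resp_world, ref_pose, cfg.head_center_offset)
    target_head = to_head_frame(speaker_pos[i0], ref_pose, cfg.head_center_offset)

    out = {
        "accepted": not compliance.rejected,
        "reason": compliance.reason,
        "t_onset": t0,
        "n_head_movements": metrics["n_movements"],
        "first_onset": metrics["first_onset"],
        "first_end_azimuth": metrics["first_end_azimuth"],
        "moved": metrics["moved"],
        "placement_error_cm": float(np.linalg.norm(target_head - pre_head)) * 100.0,
    }
    for prefix, vec in (("resp", resp_head), ("tgt", target_head), ("pre", pre_head)):
        out.update({f"{prefix}_{ax}": float(v) for ax, v in zip("xyz", vec)})
    record = err.ResponseRecord(
        response=resp_head, target=target_head,
        condition=meta["condition"], sector=meta["sector"],
        distance=meta["distance"], position_id=meta["position_id"],
    )
    out.update({k: v for k, v in err.dimension_errors(record).items() if k != "degenerate"})
    resp_sph = cartesian_to_spherical(resp_head)
    out.update(
        {
            "azimuth_response": resp_sph.azimuth,
            "elevation_response": resp_sph.elevation,
            "depth_response": resp_sph.depth,
        }
    )
    return out


def response_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Trial-level error table straight from a trial table (no kinematics).

    Uses the recorded hand response (``resp_*``) against the actual speaker
    position (``act_*``); every trial is treated as accepted.  This is the
    fast path for parameter-recovery work on track-free cohorts.
    """
    rows = []
    for _, r in trials.iterrows():
        record = err.ResponseRecord(
            response=r[["resp_x", "resp_y", "resp_z"]].to_numpy(dtype=float),
            target=r[["act_x", "act_y", "act_z"]].to_numpy(dtype=float),
            condition=r["condition"], sector=r["sector"],
            distance=r["distance"], position_id=r["position_id"],
        )
        d = err.dimension_errors(record)
        if d.pop("degenerate"):
            continue
        resp_sph = cartesian_to_spherical(record.response)
        rows.append(
            {
                "participant": r["participant"], "trial": r["trial"],
                "condition": r["condition"], "sector": r["sector"],
                "distance": r["distance"], "position_id": r["position_id"],
                "accepted": True, "reason": "none",
                **{f"resp_{ax}": record.response[i] for i, ax in enumerate("xyz")},
                **{f"tgt_{ax}": record.target[i] for i, ax in enumerate("xyz")},
                **d,
                "azimuth_response": resp_sph.azimuth,
                "elevation_response": resp_sph.elevation,
                "depth_response": resp_sph.depth,
            }
        )
    return pd.DataFrame(rows)


def summarize_3d(trial_results: pd.DataFrame, dispersion: str = "rms", by_sector: bool = False) -> pd.DataFrame:
    """Per-participant x condition (x sector) composite 3D error summaries."""
    accepted = trial_results[trial_results["accepted"]]
    keys = ["participant", "condition"] + (["sector"] if by_sector else [])
    rows = []
    for key, g in accepted.groupby(keys, sort=True):
        records = [
            err.ResponseRecord(
                response=np.array([r.resp_x, r.resp_y, r.resp_z]),
                target=np.array([r.tgt_x, r.tgt_y, r.tgt_z]),
                condition=r.condition, sector=r.sector, distance=r.distance,
                position_id=r.position_id,
            )
            for r in g.itertuples()
        ]
        summary = err.error_3d(records, dispersion=dispersion)
        row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        row.update(
            {"C_bar": summary.C_bar, "s_bar": summary.s_bar, "error_3d": summary.error_3d,
             "n_trials": summary.n_trials}
        )
        rows.append(row)
    return pd.DataFrame(rows)


def head_movement_table(trial_results: pd.DataFrame) -> pd.DataFrame:
    """Per-participant head-movement descriptives over accepted active trials."""
    active = trial_results[(trial_results["condition"] == "active") & trial_results["accepted"]]
    rows = []
    for pid, g in active.groupby("participant", sort=True):
        moving = g[g["moved"].astype(bool)]
        rows.append(
            {
                "participant": pid,
                "n_trials": len(g),
                "percent_moved": 100.0 * len(moving) / len(g) if len(g) else np.nan,
                "mean_n_movements": moving["n_head_movements"].mean() if len(moving) else np.nan,
                "mean_first_onset_ms": 1000.0 * moving["first_onset"].mean() if len(moving) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _anova_block(results_out, table, dv, within, label):
    try:
        anova = stats.rm_anova(table, dv=dv, within=within, subject="participant")
    except ValueError as exc:  # incomplete design (e.g., too few accepted trials per cell)
        log.warning("ANOVA %s skipped: %s", label, exc)
        return
    for r in anova:
        r.name = f"{label}: {r.name}"
    results_out.extend(anova)


def run_statistics(error_tab, depth_tab, summary_3d_sector, summary_3d_cond, head_tab, dispersion="rms"):
    """The study's statistical battery on participant-level tables."""
    results: list[stats.StatResult] = []

    for dim in ("azimuth", "elevation"):
        for kind in ("abs", "variable"):
            dv = f"{dim}_{kind}_error"
            _anova_block(results, error_tab, dv, ["condition", "sector"], dv)
        # planned within-sector condition contrasts on the absolute error, Holm family
        wide = error_tab.pivot_table(
            index="participant", columns=["condition", "sector"], values=f"{dim}_abs_error"
        )
        if len(wide) >= 2:
            family = {
                f"{dim}_abs front static-active": (wide[("static", "front")].to_numpy(),
                                                   wide[("active", "front")].to_numpy()),
                f"{dim}_abs back static-active": (wide[("static", "back")].to_numpy(),
                                                  wide[("active", "back")].to_numpy()),
            }
            results.extend(stats.contrast_family(family))
        else:
            log.warning("%s contrasts skipped: need >= 2 participants", dim)

    for kind in ("abs", "variable"):
        _anova_block(
            results, depth_tab, f"depth_{kind}_error",
            ["condition", "sector", "distance"], f"depth_{kind}_error",
        )
    # perceived depth separation across the three distances (GG-corrected)
    _anova_block(results, depth_tab, "depth_response_mean", ["distance"], "depth_response")

    _anova_block(results, summary_3d_sector, "error_3d", ["condition", "sector"], "error_3d")
    wide3d = summary_3d_cond.pivot_table(index="participant", columns="condition", values="error_3d")
    if len(wide3d) >= 2:
        results.extend(
            stats.contrast_family(
                {"error_3d static-active": (wide3d["static"].to_numpy(), wide3d["active"].to_numpy())}
            )
        )

    # head-movement correlations, outlier participants excluded (1.5 x IQR rule)
    extras = {}
    if len(head_tab) >= 4:
        outliers = kinematics.detect_movement_outliers(head_tab["percent_moved"].to_numpy())
        outlier_ids = head_tab.iloc[outliers]["participant"].tolist()
        kept = head_tab[~head_tab["participant"].isin(outlier_ids)]
        merged = kept.merge(
            wide3d.reset_index().rename(columns={"static": "static_3d", "active": "active_3d"}),
            on="participant",
        )
        improvement = (merged["static_3d"] - merged["active_3d"]) / merged["static_3d"]
        try:
            tau1 = stats.kendall_correlation(merged["percent_moved"], improvement)
            tau1.name = "percent_moved vs 3D improvement"
            results.append(tau1)
            tau2 = stats.kendall_correlation(merged["mean_n_movements"], merged["active_3d"])
            tau2.name = "mean_n_movements vs active 3D error"
            results.append(tau2)
        except ValueError as exc:  # zero-variance cohort (e.g., noiseless fixtures)
            log.warning("correlation skipped: %s", exc)
        extras["movement_outlier_participants"] = outlier_ids
    return results, extras


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Full reproducible run; deterministic given the config (incl. seed)."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    from . import io as sio

    if cfg.generator is not None:
        gen_cfg = dataclasses.replace(cfg.generator, seed=cfg.seed)
        log.info("generating synthetic cohort: %d participants", gen_cfg.n_participants)
        experiment = generate_experiment(gen_cfg, include_tracks=True)
        trials, tracks = experiment.trials, experiment.tracks
    elif cfg.trials_path and cfg.tracks_path:
        tracks = sio.read_tracks(cfg.tracks_path)
        trials = sio.read_trials(cfg.trials_path, tracks)
    else:
        raise ValueError("RunConfig needs either a generator config or trials+tracks paths")

    log.info("analyzing %d trials", len(trials))
    trial_results = analyze_tracks(trials, tracks, cfg)

    accepted = trial_results[trial_results["accepted"]]
    if accepted.empty:
        raise RuntimeError("errors stage: no accepted trials")
    error_tab, depth_tab = err.error_table(accepted)
    s3d_cond = summarize_3d(trial_results, cfg.dispersion, by_sector=False)
    s3d_sector = summarize_3d(trial_results, cfg.dispersion, by_sector=True)
    head_tab = head_movement_table(trial_results)
    delivered = trial_results.dropna(subset=["tgt_x"])  # all trials where sound was delivered
    placement = err.placement_accuracy(
        delivered[["pre_x", "pre_y", "pre_z"]].to_numpy(),
        delivered[["tgt_x", "tgt_y", "tgt_z"]].to_numpy(),
    )

    stat_results, stat_extras = run_statistics(
        error_tab, depth_tab, s3d_sector, s3d_cond, head_tab, cfg.dispersion
    )
    stats_table = stats.anova_table(stat_results)
    report = stats.format_report(stat_results)

    reasons = trial_results.loc[~trial_results["accepted"], "reason"].value_counts().to_dict()
    manifest = {
        "package": "soundloc3d",
        "version": _package_version(),
        "seed": cfg.seed,
        "config": _config_snapshot(cfg),
        "trials_in": int(len(trial_results)),
        "accepted": int(trial_results["accepted"].sum()),
        "rejected": int((~trial_results["accepted"]).sum()),
        "rejected_reasons": {k: int(v) for k, v in reasons.items()},
        "placement_accuracy_cm": placement,
        **stat_extras,
    }
    assert manifest["accepted"] + manifest["rejected"] == manifest["trials_in"]

    result = PipelineResult(
        trial_results=trial_results, error_table=error_tab, depth_error_table=depth_tab,
        summary_3d=pd.concat([s3d_cond.assign(sector="all"), s3d_sector], ignore_index=True),
        head_movements=head_tab, placement=placement, stat_results=stat_results,
        stats_table=stats_table, report_text=report, manifest=manifest,
    )
    if cfg.out_dir:
        _write_outputs(result, cfg)
    return result


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("soundloc3d")
    except Exception:
        return "unknown"


def _stringify_keys(obj):
    if isinstance(obj, dict):
        return {
            ("/".join(map(str, k)) if isinstance(k, tuple) else str(k)): _stringify_keys(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_stringify_keys(v) for v in obj]
    return obj


def _config_snapshot(cfg: RunConfig) -> dict:
    snap = _stringify_keys(dataclasses.asdict(cfg))
    return json.loads(json.dumps(snap, default=str))


def _write_outputs(result: PipelineResult, cfg: RunConfig) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "trial_results.csv": result.trial_results,
        "error_table.csv": result.error_table,
        "depth_error_table.csv": result.depth_error_table,
        "summary_3d.csv": result.summary_3d,
        "head_movements.csv": result.head_movements,
        "stats_report.csv": result.stats_table,
    }
    checksums = {}
    for name, tab in tables.items():
        path = out / name
        tab.to_csv(path, index=False, float_format="%.10g")
        checksums[name] = _sha256(path)
    (out / "stats_report.txt").write_text(result.report_text + "\n")
    checksums["stats_report.txt"] = _sha256(out / "stats_report.txt")
    result.manifest["checksums"] = checksums
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2, default=str) + "\n")
    with open(out / "config_snapshot.yaml", "w") as fh:
        yaml.safe_dump(_config_snapshot(cfg), fh)
    log.info("outputs written to %s", out)
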