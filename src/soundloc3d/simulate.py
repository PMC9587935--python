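"""Seeded generator of complete synthetic 3D sound-localization experiments.

The generator emulates the study design it is meant to exercise: 12
head-centered target positions (azimuths +/-30 and +/-150 deg x depths
35/55/75 cm, all at ear level), speaker placement by hand with Gaussian noise
truncated to the 2.5 cm delivery-tolerance ball, a 4-block ABBA
counterbalance of static vs. active listening (48 trials per block at the
default 8 trials per position x condition), head reorientation movements with
minimum-jerk (bell-shaped) speed profiles and configurable onset latency, and
hand-pointing responses with condition- and sector-dependent bias and
variance.  A configurable fraction of trials violates the instructions
(anticipatory hand movements; head movements in the static condition) so the
compliance stage has something to reject.

Every stochastic draw flows from the single config seed.  A GroundTruth
table records the injected biases, noise draws, movement labels and
compliance labels per trial, for parameter-recovery tests.

World-frame realism: each trial re-seats the head at a slightly different
position and yaw (the participant is unrestrained), so predetermined target
positions are variable in motion-capture coordinates but exact in
head-centered coordinates.  Tracks start 0.5 s before delivery onset; the
speaker approaches the target during the pre-roll and first satisfies the
2.5 cm criterion exactly at onset (the final sub-centimeter settle is
instantaneous between samples — only its crossing structure matters to the
gating logic), while the gaze aligns by a saccade just before.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .geometry import (
    TARGET_GRID,
    Pose,
    SphericalCoord,
    from_head_frame,
    spherical_to_cartesian,
)

__all__ = ["GeneratorConfig", "SyntheticExperiment", "generate_experiment", "generate_stimulus"]

# Trial timeline (seconds, relative to track start; delivery onset = PRE_ROLL_S)
PRE_ROLL_S = 0.5
SOUND_DURATION_S = 3.0
POST_ONSET_S = 6.0
HEAD_SAMPLE_RATE = 100.0
EYE_SAMPLE_RATE = 60.0

#: head-local translation from the tracked HMD rigid body to the ear midpoint
HEAD_CENTER_OFFSET = (0.0, -0.10, 0.0)
_MARKER_ARM = 0.10  # m, HMD marker lever arm about the head pivot

# Default response model: azimuth bias is eccentric (applied with the sign of
# the target azimuth), elevation bias is upward.  Values in deg / cm.
DEFAULT_RESPONSE_BIAS = {
    ("static", "front"): {"azimuth": 20.0, "elevation": 25.0, "depth": 0.0},
    ("active", "front"): {"azimuth": 8.0, "elevation": 12.0, "depth": 0.0},
    ("static", "back"): {"azimuth": 10.0, "elevation": 12.0, "depth": 0.0},
    ("active", "back"): {"azimuth": 10.0, "elevation": 12.0, "depth": 0.0},
}
DEFAULT_RESPONSE_SD = {
    ("static", "front"): {"azimuth": 12.0, "elevation": 22.0, "depth": 10.0},
    ("active", "front"): {"azimuth": 9.0, "elevation": 16.0, "depth": 10.0},
    ("static", "back"): {"azimuth": 17.0, "elevation": 22.0, "depth": 10.0},
    ("active", "back"): {"azimuth": 14.0, "elevation": 16.0, "depth": 10.0},
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Stated world of the synthetic experiment; defaults follow the study design."""

    n_participants: int = 20
    trials_per_cell: int = 8  # per position x condition; must be even (ABBA split)
    placement_noise_sd_cm: float = 1.2
    placement_tolerance_cm: float = 2.5
    response_bias: dict = field(default_factory=lambda: dict(DEFAULT_RESPONSE_BIAS))
    response_sd: dict = field(default_factory=lambda: dict(DEFAULT_RESPONSE_SD))
    participant_bias_sd: dict = field(
        default_factory=lambda: {"azimuth": 5.0, "elevation": 8.0, "depth": 4.0}
    )
    depth_gain: float = 0.675  # affine depth compression (response vs. physical depth)
    depth_intercept_cm: float = 18.2
    head_move_prob: float = 0.736  # mean per-trial probability in active blocks
    head_move_prob_sd: float = 0.24  # between-participant SD of that probability
    head_onset_mean_ms: float = 1077.0
    head_onset_sd_ms: float = 300.0
    movements_per_trial_mean: float = 1.2
    back_full_turn_prob: float = 0.5  # back targets: full turn vs. front-quadrant orient
    post_sound_head_move_prob: float = 0.3  # extra reorientation after sound offset
    anticipatory_rate: float = 0.06
    head_move_in_static_rate: float = 0.01
    hand_rt_mean_s: float = 3.65
    hand_rt_sd_s: float = 0.48
    head_jitter_amp_m: float = 0.0015  # postural sway amplitude; 0 for noiseless tracks
    seed: int = 0

    def __post_init__(self):
        for name in (
            "head_move_prob",
            "anticipatory_rate",
            "head_move_in_static_rate",
            "back_full_turn_prob",
            "post_sound_head_move_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.trials_per_cell < 1 or self.trials_per_cell % 2:
            raise ValueError("trials_per_cell must be a positive even number")
        if self.placement_noise_sd_cm < 0 or self.placement_tolerance_cm <= 0:
            raise ValueError("placement noise SD must be >= 0 and tolerance > 0")
        for table in (self.response_sd, self.participant_bias_sd):
            vals = table.values()
            for v in vals:
                entries = v.values() if isinstance(v, dict) else [v]
                if any(e < 0 for e in entries):
                    raise ValueError("response SDs must be >= 0")


@dataclass
class SyntheticExperiment:
    trials: pd.DataFrame
    ground_truth: pd.DataFrame
    tracks: pd.DataFrame | None
    config: GeneratorConfig


def _minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile on tau in [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _truncated_placement_noise(rng, sd_cm: float, tol_cm: float) -> np.ndarray:
    """Per-axis Gaussian placement noise (m), rejected onto the tolerance ball."""
    if sd_cm == 0.0:
        return np.zeros(3)
    while True:
        draw = rng.normal(0.0, sd_cm, size=3)
        if np.linalg.norm(draw) <= tol_cm:
            return draw / 100.0


def _block_sequence(participant_index: int) -> list[str]:
    # ABBA counterbalance: half the cohort active-static-static-active, half reversed
    if participant_index % 2 == 0:
        return ["active", "static", "static", "active"]
    return ["static", "active", "active", "static"]


def _yaw_pose(t: float, position, yaw_deg: float) -> Pose:
    return Pose(t, np.asarray(position, float), Rotation.from_euler("z", -yaw_deg, degrees=True).as_quat())


class _TrialSim:
    """Builds one trial's world-frame tracks and ground-truth labels."""

    def __init__(self, cfg: GeneratorConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.n_head = int(round((PRE_ROLL_S + POST_ONSET_S) * HEAD_SAMPLE_RATE)) + 1
        self.t_head = np.arange(self.n_head) / HEAD_SAMPLE_RATE
        self.n_eye = int(round((PRE_ROLL_S + POST_ONSET_S) * EYE_SAMPLE_RATE)) + 1
        self.t_eye = np.arange(self.n_eye) / EYE_SAMPLE_RATE

    def head_jitter(self) -> np.ndarray:
        # smooth sub-threshold postural sway, ~1.5 mm amplitude, peak speed ~5 mm/s
        rng = self.rng
        amp = self.cfg.head_jitter_amp_m * rng.uniform(0.7, 1.3, size=3)
        freq = rng.uniform(0.3, 0.5, size=3)
        phase = rng.uniform(0, 2 * np.pi, size=3)
        return amp * np.sin(2 * np.pi * freq * self.t_head[:, None] + phase)

    def head_track(self, ref_pose: Pose, movements: list[dict], jitter: np.ndarray):
        """HMD marker positions + quaternions; yaw reorientations about the pivot."""
        yaw = np.zeros(self.n_head)
        for m in movements:
            t0 = PRE_ROLL_S + m["onset"]
            tau = (self.t_head - t0) / m["duration"]
            yaw = yaw + m["amplitude"] * _minimum_jerk(tau)
        pivot = ref_pose.position + ref_pose.rotation.apply([0.0, -_MARKER_ARM, 0.0])
        rot_local = Rotation.from_euler("z", -yaw[:, None], degrees=True)  # +yaw = rightward
        rot_world = ref_pose.rotation * rot_local
        marker = pivot + rot_world.apply(np.tile([0.0, _MARKER_ARM, 0.0], (self.n_head, 1)))
        marker = marker + jitter
        return marker, rot_world.as_quat()

    def hand_track(self, rest_world: np.ndarray, response_world: np.ndarray, onset_s: float):
        """Min-jerk 3D reach from rest to the response position, then hold."""
        duration = 0.6
        tau = (self.t_head - (PRE_ROLL_S + onset_s)) / duration
        s = _minimum_jerk(tau)[:, None]
        return rest_world + s * (response_world - rest_world)

    def speaker_track(self, target_world: np.ndarray, actual_world: np.ndarray):
        """Approach during pre-roll; first within tolerance exactly at onset; retract after sound."""
        tol_m = self.cfg.placement_tolerance_cm / 100.0
        offset = actual_world - target_world
        d_act = np.linalg.norm(offset)
        u = offset / d_act if d_act > 1e-9 else np.array([1.0, 0.0, 0.0])
        pos = np.tile(actual_world, (self.n_head, 1))
        pre = self.t_head < PRE_ROLL_S
        # distance surplus: > tolerance for every pre-onset sample, 0 from onset on
        surplus = (tol_m - d_act) + 0.004 + 0.5 * (PRE_ROLL_S - self.t_head[pre])
        pos[pre] = actual_world + surplus[:, None] * u
        retract_t0 = PRE_ROLL_S + SOUND_DURATION_S + 0.2
        late = self.t_head > retract_t0
        s = _minimum_jerk((self.t_head[late] - retract_t0) / 1.0)[:, None]
        pos[late] = actual_world + s * (u + np.array([0.0, 0.0, 0.3])) * 0.4
        return pos

    def eye_track(self):
        """Gaze 10 deg down during pre-roll; saccade to straight just before onset."""
        down = np.array([0.0, np.cos(np.radians(10.0)), -np.sin(np.radians(10.0))])
        ahead = np.array([0.0, 1.0, 0.0])
        dirs = np.tile(ahead, (self.n_eye, 1))
        dirs[self.t_eye < PRE_ROLL_S - 0.03] = down
        return dirs


def _draw_head_movements(cfg, rng, target_az: float, sector: str) -> list[dict]:
    """Movement plan for one active moving trial: onset/duration/amplitude (deg)."""
    n = 1 + rng.poisson(max(cfg.movements_per_trial_mean - 1.0, 0.0))
    onset = float(np.clip(rng.normal(cfg.head_onset_mean_ms, cfg.head_onset_sd_ms) / 1000.0, 0.2, 2.3))
    if sector == "front":
        end_az = target_az + rng.normal(0.0, 5.0)
    elif rng.uniform() < cfg.back_full_turn_prob:
        end_az = target_az + rng.normal(0.0, 8.0)  # full turn (trunk involved)
    else:
        end_az = np.sign(target_az) * rng.uniform(40.0, 80.0)  # front quadrant, target side
    movements = [{"onset": onset, "duration": float(rng.uniform(0.4, 0.6)), "amplitude": float(end_az)}]
    t_next = onset + movements[0]["duration"] + rng.uniform(0.2, 0.5)
    for _ in range(n - 1):
        if t_next > 2.5:  # keep all in-window crossings safely before 3 s
            break
        movements.append(
            {
                "onset": float(t_next),
                "duration": float(rng.uniform(0.25, 0.35)),
                "amplitude": float(rng.choice([-1.0, 1.0]) * rng.uniform(12.0, 20.0)),
            }
        )
        t_next += movements[-1]["duration"] + rng.uniform(0.2, 0.5)
    return movements


def generate_experiment(config: GeneratorConfig, include_tracks: bool = True) -> SyntheticExperiment:
    """Generate a full synthetic experiment, reproducible from ``config.seed``.

    Returns the trial table (design labels, predetermined/actual speaker and
    hand-response positions in both head-centered and world frames), the
    ground-truth table, and — when ``include_tracks`` — world-frame tracks in
    the long schema (participant, trial, body, t, x, y, z, qw, qx, qy, qz).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    sim = _TrialSim(cfg, rng)
    reps_per_block = cfg.trials_per_cell // 2

    trial_rows, gt_rows, track_frames = [], [], []

    for p in range(cfg.n_participants):
        base_pos = np.array([0.0, 0.0, 1.2]) + rng.normal(0.0, 0.05, size=3)
        p_bias = {dim: rng.normal(0.0, sd) for dim, sd in cfg.participant_bias_sd.items()}
        p_move_prob = float(np.clip(rng.normal(cfg.head_move_prob, cfg.head_move_prob_sd), 0.0, 1.0))
        blocks = _block_sequence(p)
        trial_idx = 0
        for block_i, condition in enumerate(blocks):
            order = np.repeat(np.arange(len(TARGET_GRID)), reps_per_block)
            rng.shuffle(order)
            for pos_i in order:
                target = TARGET_GRID[pos_i]
                row, gt, tracks = _simulate_trial(
                    cfg, rng, sim, p, trial_idx, block_i, condition, target,
                    base_pos, p_bias, p_move_prob, include_tracks,
                )
                trial_rows.append(row)
                gt_rows.append(gt)
                if tracks is not None:
                    track_frames.append(tracks)
                trial_idx += 1

    trials = pd.DataFrame(trial_rows)
    ground_truth = pd.DataFrame(gt_rows)
    tracks = pd.concat(track_frames, ignore_index=True) if track_frames else None
    return SyntheticExperiment(trials=trials, ground_truth=ground_truth, tracks=tracks, config=cfg)


def _simulate_trial(
    cfg, rng, sim, participant, trial_idx, block_i, condition, target,
    base_pos, p_bias, p_move_prob, include_tracks,
):
    # per-trial head re-seat: unconstrained posture, small position/yaw scatter
    ref_pos = base_pos + rng.normal(0.0, 0.015, size=3)
    # re-seat yaw stays inside the 5-deg gating tolerance: the online controller
    # would not have delivered otherwise, so delivered trials are aligned by
    # construction (same logic as the placement-noise truncation)
    ref_yaw = float(np.clip(rng.normal(0.0, 2.0), -4.0, 4.0))
    ref_pose = _yaw_pose(0.0, ref_pos, ref_yaw)

    target_head = target.cartesian_m()
    noise_m = _truncated_placement_noise(rng, cfg.placement_noise_sd_cm, cfg.placement_tolerance_cm)
    actual_head = target_head + noise_m

    # response model in spherical terms around the actual sound source
    bias = cfg.response_bias[(condition, target.sector)]
    sd = cfg.response_sd[(condition, target.sector)]
    ecc = np.sign(target.azimuth)
    az_bias = ecc * bias["azimuth"] + p_bias["azimuth"]
    el_bias = bias["elevation"] + p_bias["elevation"]
    depth_bias = bias["depth"] + p_bias["depth"]
    draws = {dim: rng.normal(0.0, sd[dim]) for dim in ("azimuth", "elevation", "depth")}

    actual_sph_depth = float(np.linalg.norm(actual_head)) * 100.0
    actual_az = float(np.degrees(np.arctan2(actual_head[0], actual_head[1])))
    actual_el = float(np.degrees(np.arctan2(actual_head[2], np.hypot(actual_head[0], actual_head[1]))))
    resp_depth = cfg.depth_gain * actual_sph_depth + cfg.depth_intercept_cm + depth_bias + draws["depth"]
    resp = SphericalCoord(
        azimuth=actual_az + az_bias + draws["azimuth"],
        elevation=actual_el + el_bias + draws["elevation"],
        depth=max(resp_depth, 5.0),
    )
    resp_head = spherical_to_cartesian(resp)

    # compliance: mutually exclusive violation draws
    u = rng.uniform()
    anticipatory = u < cfg.anticipatory_rate
    head_in_static = (
        condition == "static"
        and not anticipatory
        and u < cfg.anticipatory_rate + cfg.head_move_in_static_rate
    )
    violation = (
        "anticipatory_hand" if anticipatory else "head_move_in_static" if head_in_static else "none"
    )

    movements: list[dict] = []
    moved = False
    if condition == "active" and rng.uniform() < p_move_prob:
        moved = True
        movements = _draw_head_movements(cfg, rng, target.azimuth, target.sector)
    elif head_in_static:
        onset = float(np.clip(rng.normal(cfg.head_onset_mean_ms, cfg.head_onset_sd_ms) / 1000.0, 0.3, 2.3))
        movements = [{"onset": onset, "duration": 0.5, "amplitude": float(target.azimuth)}]
    if condition == "active" and rng.uniform() < cfg.post_sound_head_move_prob:
        movements.append(
            {
                "onset": float(rng.uniform(3.3, 4.0)),
                "duration": 0.4,
                "amplitude": float(rng.choice([-1.0, 1.0]) * rng.uniform(20.0, 40.0)),
            }
        )

    if anticipatory:
        hand_onset = float(rng.uniform(1.5, 2.8))
    else:
        hand_onset = float(np.clip(rng.normal(cfg.hand_rt_mean_s, cfg.hand_rt_sd_s), 3.05, 5.0))

    in_window = [m for m in movements if m["onset"] <= 2.8]
    first = in_window[0] if in_window else None

    row = {
        "participant": participant,
        "trial": trial_idx,
        "block": block_i,
        "condition": condition,
        "position_id": f"az{int(target.azimuth)}_d{int(target.depth)}",
        "target_azimuth": target.azimuth,
        "target_depth": target.depth,
        "sector": target.sector,
        "distance": target.distance,
    }
    for prefix, vec in (("pre", target_head), ("act", actual_head), ("resp", resp_head)):
        row.update({f"{prefix}_{ax}": float(v) for ax, v in zip("xyz", vec)})

    gt = {
        "participant": participant,
        "trial": trial_idx,
        "condition": condition,
        "sector": target.sector,
        "position_id": row["position_id"],
        "az_bias_applied": float(az_bias),
        "el_bias_applied": float(el_bias),
        "depth_bias_applied": float(depth_bias),
        "az_noise": draws["azimuth"],
        "el_noise": draws["elevation"],
        "depth_noise": draws["depth"],
        "placement_noise_cm": float(np.linalg.norm(noise_m) * 100.0),
        "moved": moved,
        "n_movements_total": len(movements),
        "n_movements_in_window": len(in_window),
        "first_onset_s": first["onset"] if first else np.nan,
        "first_end_azimuth_deg": (
            float(np.sum([m["amplitude"] for m in movements[: movements.index(first) + 1]]))
            if first
            else np.nan
        ),
        "hand_onset_s": hand_onset,
        "violation": violation,
    }

    tracks = None
    if include_tracks:
        tracks = _build_tracks(cfg, sim, rng, participant, trial_idx, ref_pose, target_head,
                               actual_head, resp_head, movements, hand_onset)
    return row, gt, tracks


def _build_tracks(cfg, sim, rng, participant, trial_idx, ref_pose, target_head,
                  actual_head, resp_head, movements, hand_onset):
    # World placements are anchored at the head pose at the delivery-onset
    # sample, sway included: the online controller gated on the measured
    # head-centered position, so delivered trials satisfy the criterion in
    # the measured frame by construction.
    jitter = sim.head_jitter()
    i_onset = int(round(PRE_ROLL_S * HEAD_SAMPLE_RATE))
    onset_pose = Pose(0.0, ref_pose.position + jitter[i_onset], ref_pose.orientation)

    target_world = from_head_frame(target_head, onset_pose, HEAD_CENTER_OFFSET)
    actual_world = from_head_frame(actual_head, onset_pose, HEAD_CENTER_OFFSET)
    resp_world = from_head_frame(resp_head, onset_pose, HEAD_CENTER_OFFSET)
    center_world = from_head_frame(np.zeros(3), onset_pose, HEAD_CENTER_OFFSET)
    rest_world = center_world + onset_pose.rotation.apply([0.15, 0.25, -0.40])

    head_pos, head_quat_xyzw = sim.head_track(ref_pose, movements, jitter)
    hand_pos = sim.hand_track(rest_world, resp_world, hand_onset)
    speaker_pos = sim.speaker_track(target_world, actual_world)
    eye_dirs_local = sim.eye_track()
    eye_dirs_world = ref_pose.rotation.apply(eye_dirs_local)

    def frame(body, t, xyz, quat_xyzw=None):
        df = pd.DataFrame(
            {"participant": participant, "trial": trial_idx, "body": body, "t": t,
             "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2]}
        )
        if quat_xyzw is None:
            df[["qw", "qx", "qy", "qz"]] = np.nan
        else:
            df["qw"] = quat_xyzw[:, 3]
            df[["qx", "qy", "qz"]] = quat_xyzw[:, :3]
        return df

    return pd.concat(
        [
            frame("head", sim.t_head, head_pos, head_quat_xyzw),
            frame("hand", sim.t_head, hand_pos),
            frame("speaker", sim.t_head, speaker_pos),
            frame("eye", sim.t_eye, eye_dirs_world),
        ],
        ignore_index=True,
    )


def generate_stimulus(
    duration_s: float = 3.0,
    mod_depth: float = 0.8,
    sample_rate: int = 44100,
    mod_rate_hz: float = 2.0,
    seed: int = 0,
) -> np.ndarray:
    """Amplitude-modulated broadband burst: noise carrier x sinusoidal envelope.

    The envelope swings between (1 - mod_depth) and 1 (80% modulation gives
    0.2..1); the waveform is peak-normalized.  The modulation rate is a
    package default, not a documented property of the original stimulus.
    """
    if not 0.0 <= mod_depth <= 1.0:
        raise ValueError("mod_depth must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    carrier = rng.uniform(-1.0, 1.0, size=n)
    envelope = (1.0 - mod_depth) + mod_depth * 0.5 * (1.0 + np.sin(2 * np.pi * mod_rate_hz * t))
    wave = carrier * envelope
    return wave / np.max(np.abs(wave))
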