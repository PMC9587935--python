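"""Movement extraction from position time series.

Position tracks are low-pass filtered (zero-phase FIR), differentiated with a
two-point central difference, and segmented with a speed threshold of
80 mm/s.  Head-movement metrics (count, first onset, end direction) are taken
inside the 3-s sound window; compliance rules reject trials with anticipatory
hand movements or head movements in the static condition.

Note on the filter cutoff: head data sampled at 100 Hz puts a 50 Hz cutoff at
Nyquist, where an FIR low-pass is a near no-op.  Cutoffs at or above
0.45 x sample_rate are clamped there with a warning; the cutoff is a config
key, not a constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "SpeedSeries",
    "MovementSegment",
    "ComplianceReport",
    "lowpass_filter",
    "velocity",
    "segment_movements",
    "head_movement_metrics",
    "check_compliance",
    "detect_movement_outliers",
]

DEFAULT_CUTOFF_HZ = 50.0
DEFAULT_THRESHOLD_MM_S = 80.0
DEFAULT_MIN_DURATION_S = 0.05
SOUND_WINDOW_S = (0.0, 3.0)
_CUTOFF_CLAMP_FRACTION = 0.45


@dataclass(frozen=True)
class SpeedSeries:
    """Tangential speed (mm/s) on the source track's sampling grid.

    Endpoint samples use one-sided differences (``endpoints_one_sided``);
    interior samples are exact two-point central differences.
    """

    t: np.ndarray
    speed: np.ndarray
    endpoints_one_sided: bool = True


@dataclass(frozen=True)
class MovementSegment:
    onset: float
    offset: float
    peak_speed: float
    end_azimuth: float | None = None  # head facing azimuth at offset, deg

    def __post_init__(self):
        if not self.onset < self.offset:
            raise ValueError("segment onset must precede offset")


@dataclass(frozen=True)
class ComplianceReport:
    trial_id: object
    rejected: bool
    reason: str  # 'anticipatory_hand' | 'head_move_in_static' | 'none'


def _fir_taps(cutoff_hz: float, sample_rate: float) -> np.ndarray:
    nyq = sample_rate / 2.0
    # >= 40 dB stopband via Kaiser design; transition width capped by the
    # room left below Nyquist.
    width = min(0.2 * cutoff_hz, nyq - cutoff_hz)
    numtaps, beta = signal.kaiserord(40.0, width / nyq)
    numtaps |= 1  # force odd length (symmetric, integer group delay)
    return signal.firwin(numtaps, cutoff_hz, window=("kaiser", beta), fs=sample_rate)


def lowpass_filter(positions, sample_rate: float, cutoff_hz: float = DEFAULT_CUTOFF_HZ) -> np.ndarray:
    """Zero-phase (forward-backward) FIR low-pass of an (n,) or (n, d) track."""
    x = np.asarray(positions, dtype=float)
    if cutoff_hz >= _CUTOFF_CLAMP_FRACTION * sample_rate:
        clamped = _CUTOFF_CLAMP_FRACTION * sample_rate
        warnings.warn(
            f"cutoff {cutoff_hz} Hz at/above {_CUTOFF_CLAMP_FRACTION} x sample rate "
            f"({sample_rate} Hz); clamping to {clamped} Hz",
            RuntimeWarning,
            stacklevel=2,
        )
        cutoff_hz = clamped
    taps = _fir_taps(cutoff_hz, sample_rate)
    n = x.shape[0]
    padlen = min(3 * len(taps), n - 1)
    if n <= len(taps):
        raise ValueError(f"track too short to filter: {n} samples < {len(taps) + 1} required")
    return signal.filtfilt(taps, [1.0], x, axis=0, padlen=padlen)


def velocity(positions, sample_rate: float, t0: float = 0.0) -> SpeedSeries:
    """Two-point central-difference speed, mm/s: v[i] = |p[i+1]-p[i-1]| / (2 dt).

    Positions in meters on a uniform grid; endpoints use one-sided
    differences so the series keeps the track's length.
    """
    p = np.asarray(positions, dtype=float)
    if p.ndim == 1:
        p = p[:, None]
    n = p.shape[0]
    if n < 3:
        raise ValueError("velocity needs at least 3 samples")
    dt = 1.0 / sample_rate
    dp = np.empty_like(p)
    dp[1:-1] = (p[2:] - p[:-2]) / (2.0 * dt)
    dp[0] = (p[1] - p[0]) / dt
    dp[-1] = (p[-1] - p[-2]) / dt
    speed_mm_s = np.linalg.norm(dp, axis=1) * 1000.0
    t = t0 + np.arange(n) * dt
    return SpeedSeries(t=t, speed=speed_mm_s)


def segment_movements(
    speed: SpeedSeries,
    threshold_mm_s: float = DEFAULT_THRESHOLD_MM_S,
    min_duration_s: float = DEFAULT_MIN_DURATION_S,
) -> list[MovementSegment]:
    """Maximal runs of samples at/above the speed threshold.

    Onset/offset are the first/last sample times of each run; runs shorter
    than ``min_duration_s`` are discarded as single-sample noise crossings
    (a non-original, configurable rule — see package docs).
    """
    above = speed.speed >= threshold_mm_s
    if not above.any():
        return []
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1))
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above) - 1)
    segments = []
    for i0, i1 in zip(starts, ends):
        if i0 >= i1:  # single-sample run has zero duration
            continue
        if speed.t[i1] - speed.t[i0] < min_duration_s:
            continue
        segments.append(
            MovementSegment(
                onset=float(speed.t[i0]),
                offset=float(speed.t[i1]),
                peak_speed=float(speed.speed[i0 : i1 + 1].max()),
            )
        )
    return segments


def head_movement_metrics(
    segments: list[MovementSegment],
    facing_azimuth: tuple[np.ndarray, np.ndarray] | None = None,
    sound_window_s: tuple[float, float] = SOUND_WINDOW_S,
) -> dict:
    """Count head movements whose onset falls inside the sound window.

    Movements starting after the window (after sound emission) are removed.
    ``facing_azimuth`` is an optional ``(t, azimuth_deg)`` pair used to read
    the head's facing direction at the first movement's offset.
    """
    lo, hi = sound_window_s
    inside = [s for s in segments if lo <= s.onset <= hi]
    if not inside:
        return {"n_movements": 0, "first_onset": None, "first_end_azimuth": None, "moved": False}
    first = inside[0]
    end_az = first.end_azimuth
    if end_az is None and facing_azimuth is not None:
        t_az, az = facing_azimuth
        end_az = float(np.interp(first.offset, np.asarray(t_az, float), np.asarray(az, float)))
    return {
        "n_movements": len(inside),
        "first_onset": first.onset,
        "first_end_azimuth": end_az,
        "moved": True,
    }


def check_compliance(
    trial_id,
    condition: str,
    head_segments: list[MovementSegment] | None,
    hand_segments: list[MovementSegment] | None,
    sound_window_s: tuple[float, float] = SOUND_WINDOW_S,
) -> ComplianceReport:
    """Reject trials that violate the listening instructions.

    Static-condition trials with any head movement onset inside the sound
    window are rejected (``head_move_in_static``); in either condition a hand
    movement starting before sound offset is anticipatory.
    Segments must be referenced to delivery onset (t = 0).
    """
    if head_segments is None or hand_segments is None:
        raise ValueError(f"trial {trial_id}: head and hand segments are both required")
    lo, hi = sound_window_s
    if condition == "static" and any(lo < s.onset < hi for s in head_segments):
        return ComplianceReport(trial_id, True, "head_move_in_static")
    if any(s.onset < hi for s in hand_segments):
        return ComplianceReport(trial_id, True, "anticipatory_hand")
    return ComplianceReport(trial_id, False, "none")


def detect_movement_outliers(values, k: float = 1.5) -> np.ndarray:
    """Indices of values outside [Q1 - k*IQR, Q3 + k*IQR] (Tukey fences).

    Quartiles use linear interpolation; the fence interval is closed, so a
    constant sample yields no outliers.  Used on per-participant
    percent-head-movement values (needs >= 4 participants).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("outlier detection needs at least 4 values")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    return np.flatnonzero((x < q1 - k * iqr) | (x > q3 + k * iqr))
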