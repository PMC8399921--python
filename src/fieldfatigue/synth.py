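"""Synthetic protocol-session generator.

Produces complete sensor sessions — chest accelerometry (100 Hz, vertical x,
lateral y, sagittal z, units g), single-lead ECG (250 Hz, mV), GPS (1 Hz) and
hourly performance-test scores — for a repeated trail-run/cognitive-load
protocol, with full ground truth (fatigue trajectory, per-second activity,
terrain).  The generator is the test bed for every downstream stage: no
recorded data ship with the package.

Gait model
----------
Each step is a template waveform on step phase [0, 1): a narrow impact peak
followed by a broad mid-stance valley, superimposed on +1 g (the vertical
channel includes gravity).  The peak amplitude scales with ``1 - 0.3 * f``
for fatigue state ``f`` and the per-step amplitude/timing jitter grows with
``f``, so fatigue lowers peak vertical acceleration and raises inter-step
variability.  Surfaces select different template parameter sets (peak
sharpness, valley depth), giving surface-specific waveform families.

The waveform crosses its window mean exactly once per step in the positive
direction (outside a +/-0.05 g hysteresis band), so zero-crossing cadence
estimation recovers the commanded cadence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .config import (
    NOMINAL_CADENCE_SPM,
    OBSTACLE_DURATION_S,
    SECTION_SPEEDS_M_S,
    NominalActivity,
    Obstacle,
    ProtocolConfig,
    SlopeClass,
    Surface,
    _BASE_ALT,
    _BASE_LAT,
    _BASE_LON,
    _M_PER_DEG_LAT,
)

__all__ = [
    "FatigueTrajectory",
    "SensorSession",
    "TestDefinition",
    "DEFAULT_TEST_DEFS",
    "generate_session",
    "synth_gait_accel",
    "synth_ecg",
    "synth_test_scores",
    "default_test_schedule",
    "session_duration_s",
    "count_r_peaks",
]


# --------------------------------------------------------------------------
# fatigue trajectory
# --------------------------------------------------------------------------

@dataclass
class FatigueTrajectory:
    """Ground-truth fatigue state f(t) in [0, 1] over the session.

    The default trajectory is monotone non-decreasing (progressive fatigue
    under repeated fixed load).  ``short_term_amp`` optionally adds a bounded
    within-hour perturbation modelling partial recovery during seated blocks;
    it is off by default to keep the default trajectory monotone.
    """

    t: np.ndarray
    f: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.f.shape:
            raise ValueError("t and f must be 1-D arrays of equal length")
        if self.t.size < 2 or np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing with >= 2 points")
        if np.any(self.f < 0) or np.any(self.f > 1):
            raise ValueError("fatigue values must lie in [0, 1]")

    @property
    def duration_s(self) -> float:
        return float(self.t[-1])

    @property
    def is_monotone(self) -> bool:
        return bool(np.all(np.diff(self.f) >= 0))

    def __call__(self, times) -> np.ndarray:
        return np.interp(np.asarray(times, dtype=float), self.t, self.f)

    @classmethod
    def linear(
        cls,
        duration_s: float,
        f_start: float = 0.0,
        f_end: float = 0.6,
        short_term_amp: float = 0.0,
        lap_period_s: float = 3600.0,
        n_points: int = 512,
    ) -> "FatigueTrajectory":
        """Linear ramp from ``f_start`` to ``f_end`` over the session.

        With ``short_term_amp > 0`` a bounded sinusoidal within-lap component
        is added (and the result clipped to [0, 1]); the trajectory is then
        no longer guaranteed monotone.
        """
        t = np.linspace(0.0, float(duration_s), n_points)
        f = f_start + (f_end - f_start) * t / max(duration_s, 1e-9)
        if short_term_amp:
            f = f + short_term_amp * 0.5 * (1 - np.cos(2 * np.pi * t / lap_period_s))
        return cls(t=t, f=np.clip(f, 0.0, 1.0))


# --------------------------------------------------------------------------
# gait accelerometry
# --------------------------------------------------------------------------

# surface -> (peak_center, peak_width, valley_center, valley_width, valley_rel)
# in step-phase units; relative amplitudes of the mid-stance valley.
_SURFACE_TEMPLATES = {
    Surface.TARSEAL: (0.13, 0.050, 0.45, 0.12, 0.35),
    Surface.GRAVEL: (0.14, 0.055, 0.47, 0.13, 0.33),
    Surface.DIRT: (0.16, 0.060, 0.50, 0.13, 0.30),
    Surface.MUD: (0.19, 0.075, 0.55, 0.15, 0.25),
    Surface.GRASS: (0.17, 0.065, 0.50, 0.14, 0.28),
    Surface.BOULDERS: (0.15, 0.058, 0.42, 0.11, 0.40),
}

_BASE_AMP_G = {NominalActivity.RUN: 0.90, NominalActivity.WALK: 0.55}

#: fatigue scaling of the per-step peak amplitude: 1 - _AMP_FATIGUE_SLOPE * f
_AMP_FATIGUE_SLOPE = 0.3
_ACCEL_NOISE_G = 0.02


def synth_gait_accel(
    activity,
    surface,
    cadence_spm: float,
    fatigue: float,
    duration_s: float,
    rng,
    rate_hz: float = 100.0,
) -> np.ndarray:
    """Generate a (n, 3) gait acceleration stream [x vertical, y lateral, z sagittal].

    The vertical channel is step-periodic with fundamental ``cadence_spm/60``
    Hz; peak amplitude decreases and per-step jitter increases as
    ``fatigue`` approaches 1.
    """
    activity = NominalActivity(activity)
    surface = Surface(surface)
    if activity is NominalActivity.OBSTACLE:
        raise ValueError("gait generator handles run/walk only")
    if not 60.0 <= cadence_spm <= 220.0:
        raise ValueError("cadence must lie in [60, 220] steps/min")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if not 0.0 <= fatigue <= 1.0:
        raise ValueError("fatigue must lie in [0, 1]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    period = 60.0 / cadence_spm
    n_steps = int(np.ceil(duration_s / period)) + 3

    sigma_step = 0.02 + 0.04 * fatigue      # relative step-period jitter
    sigma_amp = 0.05 + 0.10 * fatigue       # relative amplitude jitter
    periods = period * np.clip(1.0 + sigma_step * rng.standard_normal(n_steps), 0.5, 1.5)
    starts = np.concatenate([[0.0], np.cumsum(periods)])
    base = _BASE_AMP_G[activity]
    amp = base * (1.0 - _AMP_FATIGUE_SLOPE * fatigue) * np.clip(
        1.0 + sigma_amp * rng.standard_normal(n_steps), 0.2, 2.0
    )

    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, n_steps - 1)
    phase = (t - starts[idx]) / periods[idx]

    pc, pw, vc, vw, vrel = _SURFACE_TEMPLATES[surface]
    lobe = np.exp(-0.5 * ((phase - pc) / pw) ** 2) - vrel * np.exp(
        -0.5 * ((phase - vc) / vw) ** 2
    )
    vert = 1.0 + amp[idx] * lobe + _ACCEL_NOISE_G * rng.standard_normal(n)

    # lateral sway alternates with step parity; sagittal braking/propulsion
    # follows the step cycle with a phase offset
    stride_phase = (idx + phase) / 2.0
    lat = 0.12 * base * (1.0 - _AMP_FATIGUE_SLOPE * fatigue) * np.sin(
        2 * np.pi * stride_phase
    ) + _ACCEL_NOISE_G * rng.standard_normal(n)
    sag = 0.30 * amp[idx] * (
        np.exp(-0.5 * ((phase - 0.30) / 0.10) ** 2) - 0.45
    ) + _ACCEL_NOISE_G * rng.standard_normal(n)
    return np.column_stack([vert, lat, sag])


def _synth_seated(duration_s: float, rng, rate_hz: float = 100.0) -> np.ndarray:
    """Low-variance seated accelerometry with a faint respiratory component."""
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    vert = 1.0 + 0.005 * np.sin(2 * np.pi * 0.25 * t) + 0.01 * rng.standard_normal(n)
    lat = 0.01 * rng.standard_normal(n)
    sag = 0.01 * rng.standard_normal(n)
    return np.column_stack([vert, lat, sag])


# obstacle transients: (time offset fraction, width s, amplitude g) per bump
_OBSTACLE_BUMPS = {
    Obstacle.OPEN_GATE: [(0.15, 0.15, 0.8), (0.45, 0.20, -0.6), (0.75, 0.15, 0.9)],
    Obstacle.CLIMB_GATE: [
        (0.10, 0.20, 1.4),
        (0.30, 0.15, -1.0),
        (0.50, 0.25, 1.6),
        (0.70, 0.15, -0.9),
        (0.85, 0.20, 1.2),
    ],
}


def _synth_obstacle(kind: Obstacle, duration_s: float, rng, rate_hz: float = 100.0) -> np.ndarray:
    """One-off stereotyped transient for a gate crossing."""
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    vert = 1.0 + 0.05 * rng.standard_normal(n)
    for frac, width, ampl in _OBSTACLE_BUMPS[kind]:
        vert += ampl * np.exp(-0.5 * ((t - frac * duration_s) / width) ** 2)
    lat = 0.15 * rng.standard_normal(n)
    sag = 0.15 * rng.standard_normal(n)
    return np.column_stack([vert, lat, sag])


# --------------------------------------------------------------------------
# ECG
# --------------------------------------------------------------------------

# PQRST template as Gaussians on beat phase: (center, width, amplitude mV)
_ECG_TEMPLATE = [
    (0.18, 0.025, 0.12),   # P
    (0.355, 0.009, -0.18),  # Q
    (0.375, 0.009, 1.10),   # R
    (0.395, 0.010, -0.25),  # S
    (0.60, 0.045, 0.32),    # T
]


def synth_ecg(
    hr_profile_bpm,
    duration_s: float,
    rng,
    rate_hz: float = 250.0,
    wander_amp_mv: float = 0.10,
    noise_sd_mv: float = 0.01,
) -> np.ndarray:
    """Synthetic single-lead ECG (mV) whose instantaneous rate tracks ``hr_profile_bpm``.

    ``hr_profile_bpm`` is a scalar or a 1 Hz series covering the duration.
    Additive low-frequency baseline wander (amplitude ``wander_amp_mv``) and
    white noise exercise the downstream baseline correction.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    hr = np.asarray(hr_profile_bpm, dtype=float)
    if hr.ndim == 0:
        hr_t = np.full(n, float(hr))
    else:
        hr_t = np.interp(t, np.arange(hr.size, dtype=float), hr)
    if np.any(hr_t < 40.0) or np.any(hr_t > 210.0):
        raise ValueError("heart-rate profile must lie in [40, 210] bpm")

    beat_phase = np.cumsum(hr_t / 60.0) / rate_hz
    wrapped = np.mod(beat_phase, 1.0)
    ecg = np.zeros(n)
    for c, w, a in _ECG_TEMPLATE:
        ecg += a * np.exp(-0.5 * ((wrapped - c) / w) ** 2)
    if wander_amp_mv:
        ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
        ecg += wander_amp_mv * np.sin(2 * np.pi * 0.20 * t + ph1)
        ecg += 0.4 * wander_amp_mv * np.sin(2 * np.pi * 0.08 * t + ph2)
    ecg += noise_sd_mv * rng.standard_normal(n)
    return ecg


def count_r_peaks(ecg: np.ndarray, rate_hz: float = 250.0, max_hr_bpm: float = 220.0) -> int:
    """Generator self-check: count R peaks by thresholded local maxima."""
    from scipy.signal import find_peaks

    x = np.asarray(ecg, dtype=float)
    height = 0.5 * np.percentile(x, 99.9)
    distance = int(rate_hz * 60.0 / max_hr_bpm)
    peaks, _ = find_peaks(x, height=height, distance=distance)
    return int(peaks.size)


# --------------------------------------------------------------------------
# performance-test scores
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TestDefinition:
    """Affine score model: score = baseline + slope * f(t) + N(0, noise_sd).

    Slopes and noise levels are calibrated so the regenerated sensitivity
    pattern ranks like the field battery: vertical jump and dominant-hand
    finger tapping highly protocol-sensitive, PVSAT and spatial memory near
    zero.
    """

    baseline: float
    slope_per_f: float
    noise_sd: float
    phases: tuple[str, ...] = ("post_physical", "post_cognitive")


DEFAULT_TEST_DEFS: dict[str, TestDefinition] = {
    "jump_height": TestDefinition(42.0, -15.0, 1.39, phases=("post_physical",)),
    "ftt_dominant": TestDefinition(62.0, -20.0, 2.18),
    "ftt_nondominant": TestDefinition(55.0, -14.0, 2.26),
    "stroop": TestDefinition(720.0, 180.0, 32.0),
    "trail_making_a": TestDefinition(28.0, 12.0, 4.3),
    "trail_making_b": TestDefinition(55.0, 3.0, 2.3),
    "pvsat": TestDefinition(52.0, -1.2, 1.19),
    "spatial_memory": TestDefinition(6.5, -0.3, 0.52),
}


def synth_test_scores(
    trajectory: FatigueTrajectory,
    schedule: Sequence[tuple[float, str]],
    rng,
    test_defs: Optional[dict[str, TestDefinition]] = None,
    noise_scale: float = 1.0,
) -> pd.DataFrame:
    """Generate the performance-test score table for a session.

    ``schedule`` is a sequence of (time_s, phase) administration slots;
    each applicable test contributes one row per slot.
    """
    if len(schedule) == 0:
        raise ValueError("test schedule must be non-empty")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    test_defs = DEFAULT_TEST_DEFS if test_defs is None else test_defs
    rows = []
    for t_s, phase in schedule:
        if not 0.0 <= t_s <= trajectory.duration_s + 1e-6:
            raise ValueError("schedule time outside the session span")
        f = float(trajectory(t_s))
        for name, d in test_defs.items():
            if phase not in d.phases:
                continue
            score = d.baseline + d.slope_per_f * f
            score += noise_scale * d.noise_sd * rng.standard_normal()
            rows.append((float(t_s), name, phase, float(score)))
    return pd.DataFrame(rows, columns=["time_s", "test_name", "phase", "score"])


# --------------------------------------------------------------------------
# session assembly
# --------------------------------------------------------------------------

@dataclass
class _Segment:
    lap: int
    section_id: int           # -1 for the seated block
    composite: str            # composite activity name
    nominal: str              # run | walk | sit | obstacle
    surface: Optional[Surface]
    slope: Optional[SlopeClass]
    obstacle: Optional[Obstacle]
    start_s: int
    duration_s: int
    length_m: float


@dataclass
class SensorSession:
    """One synthetic protocol run: aligned raw streams plus ground truth."""

    config: ProtocolConfig
    trajectory: FatigueTrajectory
    accel: np.ndarray          # (n, 3) g at accel_rate_hz
    accel_rate_hz: float
    ecg: np.ndarray            # (n,) mV at ecg_rate_hz
    ecg_rate_hz: float
    gps: pd.DataFrame          # 1 Hz: time_s, lat, lon, alt
    test_scores: pd.DataFrame  # time_s, test_name, phase, score
    truth: pd.DataFrame        # per second: time_s, activity, ...
    duration_s: int


def _segment_schedule(config: ProtocolConfig) -> list[_Segment]:
    segments: list[_Segment] = []
    t = 0
    for lap in range(config.n_laps):
        for sid, sec in enumerate(config.sections):
            if sec.nominal_activity is NominalActivity.OBSTACLE:
                dur = int(round(OBSTACLE_DURATION_S[sec.obstacle]))
                composite = sec.obstacle.value
                nominal = "obstacle"
            else:
                speed = SECTION_SPEEDS_M_S[(sec.nominal_activity, sec.slope_class)]
                dur = max(1, int(round(sec.length_m / speed)))
                suffix = "" if sec.slope_class is SlopeClass.FLAT else f"_{sec.slope_class.value}"
                composite = sec.nominal_activity.value + suffix
                nominal = sec.nominal_activity.value
            segments.append(
                _Segment(lap, sid, composite, nominal, sec.surface, sec.slope_class,
                         sec.obstacle, t, dur, sec.length_m)
            )
            t += dur
        sit = int(round(config.sit_duration_s))
        segments.append(_Segment(lap, -1, "sit", "sit", None, None, None, t, sit, 0.0))
        t += sit
    return segments


def session_duration_s(config: ProtocolConfig) -> int:
    """Total session duration in whole seconds for the given protocol."""
    segs = _segment_schedule(config)
    return segs[-1].start_s + segs[-1].duration_s


def default_test_schedule(config: ProtocolConfig) -> list[tuple[float, str]]:
    """Hourly administration slots: post-physical at traversal end, post-cognitive
    after the seated block."""
    slots: list[tuple[float, str]] = []
    for seg in _segment_schedule(config):
        if seg.composite == "sit":
            slots.append((float(seg.start_s), "post_physical"))
            slots.append((float(seg.start_s + seg.duration_s), "post_cognitive"))
    return slots


# heart-rate drive per composite activity (fraction of reserve)
_HR_INTENSITY = {
    "sit": 0.10, "walk": 0.45, "walk_up": 0.60, "walk_down": 0.45,
    "run": 0.75, "run_up": 0.90, "run_down": 0.70,
    "open_gate": 0.60, "climb_gate": 0.65,
}


def _hr_profile(segments: list[_Segment], trajectory: FatigueTrajectory, total_s: int) -> np.ndarray:
    t_sec = np.arange(total_s, dtype=float)
    intensity = np.empty(total_s)
    for seg in segments:
        intensity[seg.start_s: seg.start_s + seg.duration_s] = _HR_INTENSITY[seg.composite]
    hr = 55.0 + 110.0 * intensity + 15.0 * trajectory(t_sec)
    # first-order cardiac lag: 30 s moving average, edge-padded
    k = 30
    padded = np.concatenate([np.full(k // 2, hr[0]), hr, np.full(k - k // 2 - 1, hr[-1])])
    hr = np.convolve(padded, np.ones(k) / k, mode="valid")
    return np.clip(hr, 45.0, 200.0)


def _gps_track(
    config: ProtocolConfig, segments: list[_Segment], total_s: int, rng
) -> pd.DataFrame:
    lengths = np.array([s.length_m for s in config.sections])
    cum_d = np.concatenate([[0.0], np.cumsum(lengths)])
    cum_a = np.concatenate([[0.0], np.cumsum([s.climb_m for s in config.sections])])
    loop = cum_d[-1]

    dist = np.zeros(total_s)
    for seg in segments:
        sl = slice(seg.start_s, seg.start_s + seg.duration_s)
        if seg.section_id < 0:  # seated: stationary at loop origin
            dist[sl] = 0.0
        else:
            within = cum_d[seg.section_id] + seg.length_m * (
                np.arange(seg.duration_s) + 1.0
            ) / seg.duration_s
            dist[sl] = within
    d_mod = np.mod(dist, loop)
    radius = loop / (2 * np.pi)
    theta = 2 * np.pi * d_mod / loop
    x = radius * np.cos(theta) - radius
    y = radius * np.sin(theta)
    alt = _BASE_ALT + np.interp(d_mod, cum_d, cum_a)

    lat = _BASE_LAT + y / _M_PER_DEG_LAT
    lon = _BASE_LON + x / (_M_PER_DEG_LAT * np.cos(np.radians(_BASE_LAT)))
    # horizontal accuracy ~6 m -> per-axis noise sd 2.5 m; altimeter sd 3 m
    lat = lat + rng.normal(0.0, 2.5, total_s) / _M_PER_DEG_LAT
    lon = lon + rng.normal(0.0, 2.5, total_s) / (
        _M_PER_DEG_LAT * np.cos(np.radians(_BASE_LAT))
    )
    alt = alt + rng.normal(0.0, 3.0, total_s)
    return pd.DataFrame(
        {"time_s": np.arange(total_s, dtype=float), "lat": lat, "lon": lon, "alt": alt}
    )


def generate_session(
    config: ProtocolConfig, trajectory: Optional[FatigueTrajectory] = None
) -> SensorSession:
    """Generate a complete synthetic protocol session.

    The per-second true schedule alternates run/walk sections over the course
    plus a seated block per lap.  All randomness derives from ``config.seed``
    through a fixed stream-splitting scheme, so identical (config, trajectory)
    pairs produce bit-identical sessions.
    """
    segments = _segment_schedule(config)
    total_s = segments[-1].start_s + segments[-1].duration_s
    if trajectory is None:
        trajectory = FatigueTrajectory.linear(total_s)
    elif trajectory.duration_s < total_s - 1e-6:
        raise ValueError(
            f"trajectory covers {trajectory.duration_s:.0f} s but the session "
            f"lasts {total_s} s"
        )

    ss = np.random.SeedSequence(config.seed)
    rng_accel, rng_ecg, rng_gps, rng_scores = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )

    # accelerometry, segment by segment
    chunks = []
    per_seg_cadence = []
    for seg in segments:
        f_mid = float(trajectory(seg.start_s + seg.duration_s / 2.0))
        if seg.nominal == "sit":
            chunks.append(_synth_seated(seg.duration_s, rng_accel, config.accel_rate_hz))
            per_seg_cadence.append(0.0)
        elif seg.nominal == "obstacle":
            chunks.append(
                _synth_obstacle(seg.obstacle, seg.duration_s, rng_accel, config.accel_rate_hz)
            )
            per_seg_cadence.append(0.0)
        else:
            cadence = NOMINAL_CADENCE_SPM[NominalActivity(seg.nominal)]
            cadence += float(rng_accel.uniform(-2.0, 2.0))
            chunks.append(
                synth_gait_accel(
                    seg.nominal, seg.surface, cadence, f_mid, seg.duration_s,
                    rng_accel, config.accel_rate_hz,
                )
            )
            per_seg_cadence.append(cadence)
    accel = np.concatenate(chunks, axis=0)

    hr = _hr_profile(segments, trajectory, total_s)
    ecg = synth_ecg(hr, total_s, rng_ecg, config.ecg_rate_hz)

    gps = _gps_track(config, segments, total_s, rng_gps)

    schedule = default_test_schedule(config)
    scores = synth_test_scores(trajectory, schedule, rng_scores)

    # per-second truth
    t_sec = np.arange(total_s)
    activity = np.empty(total_s, dtype=object)
    nominal = np.empty(total_s, dtype=object)
    surface = np.empty(total_s, dtype=object)
    slope = np.empty(total_s, dtype=object)
    section = np.full(total_s, -1, dtype=int)
    lap = np.zeros(total_s, dtype=int)
    obstacle = np.empty(total_s, dtype=object)
    cadence_truth = np.zeros(total_s)
    for seg, cad in zip(segments, per_seg_cadence):
        sl = slice(seg.start_s, seg.start_s + seg.duration_s)
        activity[sl] = seg.composite
        nominal[sl] = seg.nominal
        surface[sl] = seg.surface.value if seg.surface else ""
        slope[sl] = seg.slope.value if seg.slope else ""
        section[sl] = seg.section_id
        lap[sl] = seg.lap
        obstacle[sl] = seg.obstacle.value if seg.obstacle else ""
        cadence_truth[sl] = cad
    truth = pd.DataFrame(
        {
            "time_s": t_sec,
            "activity": activity,
            "nominal": nominal,
            "surface": surface,
            "slope": slope,
            "section_id": section,
            "lap": lap,
            "obstacle": obstacle,
            "cadence_spm": cadence_truth,
            "fatigue": trajectory(t_sec.astype(float)),
        }
    )

    return SensorSession(
        config=config,
        trajectory=trajectory,
        accel=accel,
        accel_rate_hz=config.accel_rate_hz,
        ecg=ecg,
        ecg_rate_hz=config.ecg_rate_hz,
        gps=gps,
        test_scores=scores,
        truth=truth,
        duration_s=total_s,
    )
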