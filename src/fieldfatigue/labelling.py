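"""Per-second activity, terrain and section labelling.

Gait class comes from vertical-axis cadence (zero crossings of the
mean-removed signal, 100 < walk < 150 < run steps/min), sections from GPS
closest-approach to the course waypoints, and slope class from mean GPS
altitude at the bounding waypoints.  Label resolution is one second.

Crossing counting uses a small hysteresis band (default +/-0.05 g): a
positive-going crossing is registered when the signal rises above ``+h``
having last been below ``-h``.  Without the band, low-variance seated noise
produces spurious crossings at the sample rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import (
    COMPOSITE_ACTIVITIES,
    NominalActivity,
    SectionSpec,
    SlopeClass,
)

__all__ = [
    "positive_crossing_indices",
    "cadence_from_zero_crossings",
    "classify_activity",
    "assign_sections",
    "slope_class_from_altitude",
    "build_timeline",
    "composite_activities",
    "timeline_gait_agreement",
]

DEFAULT_HYSTERESIS_G = 0.05
WALK_THRESHOLD_SPM = 100.0
RUN_THRESHOLD_SPM = 150.0


def positive_crossing_indices(x: np.ndarray, hysteresis: float = 0.0) -> np.ndarray:
    """Indices of positive-going crossings of zero with a +/-hysteresis band.

    A crossing is the first sample above ``+hysteresis`` after the signal was
    last below ``-hysteresis``.  With ``hysteresis=0`` this reduces to plain
    sign-change detection (zeros carry the previous sign).
    """
    x = np.asarray(x, float)
    if hysteresis == 0.0:
        s = np.where(x > 0, 1, np.where(x < 0, -1, 0))
    else:
        s = np.where(x > hysteresis, 1, np.where(x < -hysteresis, -1, 0))
    nz = np.flatnonzero(s)
    if nz.size < 2:
        return np.empty(0, dtype=int)
    vals = s[nz]
    trans = (vals[1:] == 1) & (vals[:-1] == -1)
    return nz[1:][trans]


def cadence_from_zero_crossings(
    vertical_accel: np.ndarray,
    rate_hz: float,
    window_s: float = 5.0,
    hysteresis: float = DEFAULT_HYSTERESIS_G,
    n_seconds: Optional[int] = None,
    mode: str = "refined",
) -> np.ndarray:
    """Cadence (steps/min), one value per second, from a sliding centered window.

    Each window is mean-removed before crossing detection.  ``mode="refined"``
    estimates cadence from the span between the first and last crossing,
    ``60 * (c - 1) / dt``, which resolves below the count granularity of the
    window; ``mode="count"`` returns the plain ``crossings * 60 / window_s``.
    """
    x = np.asarray(vertical_accel, float)
    if window_s < 2.0:
        raise ValueError("cadence window must be at least 2 s")
    w = int(round(window_s * rate_hz))
    if w > x.size:
        raise ValueError("cadence window longer than the series")
    if mode not in ("refined", "count"):
        raise ValueError(f"unknown cadence mode {mode!r}")
    total_sec = int(x.size // rate_hz)
    if n_seconds is None:
        n_seconds = total_sec
    out = np.zeros(n_seconds)
    for s in range(n_seconds):
        center = int(round((s + 0.5) * rate_hz))
        lo = min(max(0, center - w // 2), x.size - w)
        win = x[lo: lo + w]
        win = win - win.mean()
        idx = positive_crossing_indices(win, hysteresis)
        c = idx.size
        if mode == "refined" and c >= 2:
            dt = (idx[-1] - idx[0]) / rate_hz
            out[s] = 60.0 * (c - 1) / dt
        else:
            out[s] = 60.0 * c / window_s
    return out


def classify_activity(cadence_spm) -> np.ndarray:
    """Map cadence to gait class: <=100 other, (100, 150) walk, >=150 run.

    The printed inequality chain is read strictly: exactly 100 -> other,
    exactly 150 -> run.
    """
    c = np.asarray(cadence_spm, float)
    if np.any(c < 0):
        raise ValueError("cadence must be non-negative")
    out = np.full(c.shape, "other", dtype=object)
    out[(c > WALK_THRESHOLD_SPM) & (c < RUN_THRESHOLD_SPM)] = "walk"
    out[c >= RUN_THRESHOLD_SPM] = "run"
    if np.ndim(cadence_spm) == 0:
        return out.item()
    return out


# --------------------------------------------------------------------------
# GPS: sections and slope
# --------------------------------------------------------------------------

_EARTH_R = 6371000.0


def haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in metres."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return 2 * _EARTH_R * np.arcsin(np.sqrt(a))


def _track_kinematics(gps: pd.DataFrame, smooth_s: int = 11, moving_speed: float = 0.5):
    """Smoothed positions, per-second speed, movement mask and moving cumdist."""
    lat = gps["lat"].to_numpy(float)
    lon = gps["lon"].to_numpy(float)
    k = min(smooth_s, lat.size) | 1
    kern = np.ones(k) / k
    pad = k // 2
    lat_s = np.convolve(np.pad(lat, pad, mode="edge"), kern, mode="valid")
    lon_s = np.convolve(np.pad(lon, pad, mode="edge"), kern, mode="valid")
    step = np.zeros(lat.size)
    step[1:] = haversine_m(lat_s[:-1], lon_s[:-1], lat_s[1:], lon_s[1:])
    dt = np.gradient(gps["time_s"].to_numpy(float))
    speed = step / np.maximum(dt, 1e-9)
    moving = speed > moving_speed
    cumdist = np.cumsum(np.where(moving, step, 0.0))
    return lat_s, lon_s, speed, moving, cumdist


def assign_sections(
    gps: pd.DataFrame,
    sections: Sequence[SectionSpec],
    n_laps: int,
    gap_threshold_m: float = 50.0,
    search_frac: float = 0.12,
) -> pd.DataFrame:
    """Closest-approach crossing time for every (lap, waypoint).

    The search for each crossing is restricted to a window of cumulative
    moving track distance around the waypoint's expected along-course
    position (per-lap length self-calibrated from the track), so repeated
    laps do not alias.  Approaches farther than ``gap_threshold_m`` are
    flagged rather than silently assigned.
    """
    lat_s, lon_s, _, moving, cumdist = _track_kinematics(gps)
    times = gps["time_s"].to_numpy(float)
    loop_len = float(sum(s.length_m for s in sections))
    wp_dist = np.concatenate([[0.0], np.cumsum([s.length_m for s in sections])])[:-1]
    lap_len_hat = cumdist[-1] / n_laps
    margin = search_frac * lap_len_hat

    rows = []
    for lap in range(n_laps):
        for wi, sec in enumerate(sections):
            expected = (lap + wp_dist[wi] / loop_len) * lap_len_hat
            lo, hi = expected - margin, expected + margin
            mask = (cumdist >= lo) & (cumdist <= hi)
            if wi == 0:
                # lap start: participant is stationary at the origin between
                # laps; restrict to moving samples so the crossing lands at
                # the start of the traversal
                mask &= moving | (times == times[0])
            if not mask.any():
                rows.append((lap, wi, np.nan, np.nan, True))
                continue
            cand = np.flatnonzero(mask)
            d = haversine_m(
                lat_s[cand], lon_s[cand], sec.waypoint_start.lat, sec.waypoint_start.lon
            )
            j = int(np.argmin(d))
            rows.append((lap, wi, float(times[cand[j]]), float(d[j]), bool(d[j] > gap_threshold_m)))
    return pd.DataFrame(rows, columns=["lap", "waypoint", "time_s", "min_dist_m", "flagged"])


def slope_class_from_altitude(
    gps: pd.DataFrame,
    t_start_s: float,
    t_end_s: float,
    horizontal_length_m: float,
    n_avg: int = 9,
    flat_grade: float = 0.02,
) -> str:
    """Slope class of a section from mean GPS altitude at its waypoints.

    Altitude is averaged over the ``n_avg`` fixes nearest each crossing time;
    ``|grade| < flat_grade`` maps to flat, otherwise the sign decides.
    """
    times = gps["time_s"].to_numpy(float)
    alt = gps["alt"].to_numpy(float)

    def _mean_alt(t0: float) -> float:
        order = np.argsort(np.abs(times - t0))[:n_avg]
        if order.size < 3:
            raise ValueError("need at least 3 altitude samples near each waypoint")
        return float(alt[order].mean())

    grade = (_mean_alt(t_end_s) - _mean_alt(t_start_s)) / horizontal_length_m
    if abs(grade) < flat_grade:
        return SlopeClass.FLAT.value
    return SlopeClass.UP.value if grade > 0 else SlopeClass.DOWN.value


# --------------------------------------------------------------------------
# timeline assembly
# --------------------------------------------------------------------------

@dataclass
class ActivityTimeline:
    """Per-second labels for one session."""

    records: pd.DataFrame  # time_s, cadence_spm, gait, slope, surface,
    #                        section_id, lap, obstacle, composite

    def __len__(self) -> int:
        return len(self.records)


def build_timeline(
    vertical_accel: np.ndarray,
    accel_rate_hz: float,
    gps: pd.DataFrame,
    sections: Sequence[SectionSpec],
    n_laps: int,
    cadence_window_s: float = 5.0,
    hysteresis: float = DEFAULT_HYSTERESIS_G,
) -> ActivityTimeline:
    """Label every second of the session from sensors alone (no ground truth).

    Obstacle seconds are taken from the course configuration (the sections
    flagged as obstacle crossings); there is no waveform-based obstacle
    detector.  Slope class per section is estimated from GPS altitude and
    averaged across laps.
    """
    n_sec = int(min(len(gps), np.floor(len(vertical_accel) / accel_rate_hz)))
    cadence = cadence_from_zero_crossings(
        vertical_accel, accel_rate_hz, cadence_window_s, hysteresis, n_seconds=n_sec
    )
    gait = classify_activity(cadence)
    _, _, _, moving, _ = _track_kinematics(gps)
    crossings = assign_sections(gps, sections, n_laps)

    section_id = np.full(n_sec, -1, dtype=int)
    lap_arr = np.full(n_sec, -1, dtype=int)
    cr = crossings.dropna(subset=["time_s"]).sort_values("time_s").reset_index(drop=True)
    for i in range(len(cr) - 1):
        t0, t1 = int(cr.loc[i, "time_s"]), int(cr.loc[i + 1, "time_s"])
        sl = slice(max(0, t0), min(n_sec, t1))
        section_id[sl] = int(cr.loc[i, "waypoint"])
        lap_arr[sl] = int(cr.loc[i, "lap"])
    if len(cr):
        t_last = int(cr.loc[len(cr) - 1, "time_s"])
        section_id[t_last:n_sec] = int(cr.loc[len(cr) - 1, "waypoint"])
        lap_arr[t_last:n_sec] = int(cr.loc[len(cr) - 1, "lap"])

    # slope per section: altitude-derived, averaged over laps by majority vote
    slope_by_section: dict[int, str] = {}
    for wi, sec in enumerate(sections):
        if sec.nominal_activity is NominalActivity.OBSTACLE:
            slope_by_section[wi] = SlopeClass.FLAT.value
            continue
        votes = []
        for lap in range(n_laps):
            row0 = cr[(cr["lap"] == lap) & (cr["waypoint"] == wi)]
            wnext, lnext = (wi + 1, lap) if wi + 1 < len(sections) else (0, lap + 1)
            row1 = cr[(cr["lap"] == lnext) & (cr["waypoint"] == wnext)]
            if row0.empty or row1.empty:
                continue
            votes.append(
                slope_class_from_altitude(
                    gps, float(row0["time_s"].iloc[0]), float(row1["time_s"].iloc[0]),
                    sec.length_m,
                )
            )
        if votes:
            vals, counts = np.unique(votes, return_counts=True)
            slope_by_section[wi] = str(vals[np.argmax(counts)])
        else:
            slope_by_section[wi] = SlopeClass.FLAT.value

    surface = np.array(
        [sections[s].surface.value if s >= 0 else "" for s in section_id], dtype=object
    )
    obstacle = np.array(
        [
            sections[s].obstacle.value
            if s >= 0 and sections[s].obstacle is not None
            else ""
            for s in section_id
        ],
        dtype=object,
    )
    slope = np.array(
        [slope_by_section.get(s, SlopeClass.FLAT.value) if s >= 0 else "" for s in section_id],
        dtype=object,
    )

    composite = np.empty(n_sec, dtype=object)
    for s in range(n_sec):
        if obstacle[s]:
            composite[s] = obstacle[s]
        elif gait[s] in ("run", "walk"):
            suffix = "" if slope[s] in ("", "flat") else f"_{slope[s]}"
            composite[s] = gait[s] + suffix
        elif not moving[min(s, len(moving) - 1)]:
            composite[s] = "sit"
        else:
            composite[s] = "other"

    records = pd.DataFrame(
        {
            "time_s": np.arange(n_sec),
            "cadence_spm": cadence,
            "gait": gait,
            "slope": slope,
            "surface": surface,
            "section_id": section_id,
            "lap": lap_arr,
            "obstacle": obstacle,
            "composite": composite,
        }
    )
    return ActivityTimeline(records=records)


def composite_activities(timeline: ActivityTimeline) -> dict[str, np.ndarray]:
    """Partition labelled seconds into the composite-activity vocabulary.

    Returns a mapping from composite name to the (time-ordered) seconds
    belonging to it; member sets are disjoint by construction.
    """
    rec = timeline.records
    out: dict[str, np.ndarray] = {}
    for name in COMPOSITE_ACTIVITIES:
        t = rec.loc[rec["composite"] == name, "time_s"].to_numpy(int)
        if t.size:
            out[name] = t
    return out


def timeline_gait_agreement(
    timeline: ActivityTimeline, truth: pd.DataFrame, margin_s: int = 2
) -> float:
    """Fraction of seconds whose cadence-derived gait class matches the
    generated schedule, excluding ``margin_s`` seconds around every true
    activity transition and all obstacle seconds."""
    n = min(len(timeline.records), len(truth))
    pred = timeline.records["gait"].to_numpy(object)[:n]
    nominal = truth["nominal"].to_numpy(object)[:n]
    expected = np.where(
        nominal == "run", "run", np.where(nominal == "walk", "walk", "other")
    ).astype(object)
    keep = nominal != "obstacle"
    change = np.flatnonzero(nominal[1:] != nominal[:-1]) + 1
    for c in change:
        keep[max(0, c - margin_s): min(n, c + margin_s)] = False
    return float(np.mean(pred[keep] == expected[keep]))
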