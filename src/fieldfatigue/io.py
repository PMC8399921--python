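"""Readers and writers for the session on-disk layout.

A session directory contains::

    accel.csv          time_s, accel_x, accel_y, accel_z   (g, 100 Hz)
    ecg.csv            time_s, ecg_mv                      (mV, 250 Hz)
    gps.gpx            GPX 1.1 track (1 Hz) + course waypoints
    test_scores.csv    time_s, test_name, phase, score
    truth_timeline.csv per-second generator truth (synthetic sessions only)
    trajectory.csv     t_s, fatigue (synthetic sessions only)
    manifest.yaml      rates, seed, lap count, config hash

Real exported sensor CSVs with the same column contract load through the
same readers.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Optional
from xml.etree import ElementTree as ET

import numpy as np
import pandas as pd
import yaml

from .synth import FatigueTrajectory, SensorSession

__all__ = [
    "write_session",
    "load_session",
    "write_gpx",
    "read_gpx",
    "write_label_series",
    "config_hash",
]

_GPX_NS = "http://www.topografix.com/GPX/1/1"
_T0 = datetime(2021, 3, 1, 6, 0, 0, tzinfo=timezone.utc)


def config_hash(obj) -> str:
    """Stable sha256 of a configuration mapping."""
    return hashlib.sha256(
        yaml.safe_dump(obj, sort_keys=True).encode()
    ).hexdigest()[:16]


def write_gpx(path, gps: pd.DataFrame, waypoints=None) -> None:
    """Write a 1 Hz track (and optional course waypoints) as GPX 1.1."""
    ET.register_namespace("", _GPX_NS)
    root = ET.Element(f"{{{_GPX_NS}}}gpx", version="1.1", creator="fieldfatigue")
    if waypoints:
        for i, wp in enumerate(waypoints):
            w = ET.SubElement(root, f"{{{_GPX_NS}}}wpt",
                              lat=f"{wp.lat:.7f}", lon=f"{wp.lon:.7f}")
            ET.SubElement(w, f"{{{_GPX_NS}}}ele").text = f"{wp.alt:.2f}"
            ET.SubElement(w, f"{{{_GPX_NS}}}name").text = f"WP{i:02d}"
    trk = ET.SubElement(root, f"{{{_GPX_NS}}}trk")
    seg = ET.SubElement(trk, f"{{{_GPX_NS}}}trkseg")
    for row in gps.itertuples(index=False):
        pt = ET.SubElement(seg, f"{{{_GPX_NS}}}trkpt",
                           lat=f"{row.lat:.7f}", lon=f"{row.lon:.7f}")
        ET.SubElement(pt, f"{{{_GPX_NS}}}ele").text = f"{row.alt:.2f}"
        stamp = _T0 + timedelta(seconds=float(row.time_s))
        ET.SubElement(pt, f"{{{_GPX_NS}}}time").text = stamp.strftime("%Y-%m-%dT%H:%M:%SZ")
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


def read_gpx(path) -> pd.DataFrame:
    """Read a GPX 1.1 track back into (time_s, lat, lon, alt)."""
    root = ET.parse(path).getroot()
    rows = []
    for pt in root.iter(f"{{{_GPX_NS}}}trkpt"):
        ele = pt.find(f"{{{_GPX_NS}}}ele")
        tm = pt.find(f"{{{_GPX_NS}}}time")
        stamp = datetime.strptime(tm.text, "%Y-%m-%dT%H:%M:%SZ").replace(
            tzinfo=timezone.utc
        )
        rows.append(
            (
                (stamp - _T0).total_seconds(),
                float(pt.attrib["lat"]),
                float(pt.attrib["lon"]),
                float(ele.text) if ele is not None else np.nan,
            )
        )
    return pd.DataFrame(rows, columns=["time_s", "lat", "lon", "alt"])


def write_session(out_dir, session: SensorSession) -> Path:
    """Write a session to its directory layout; returns the directory path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_a = session.accel.shape[0]
    pd.DataFrame(
        {
            "time_s": np.arange(n_a) / session.accel_rate_hz,
            "accel_x": session.accel[:, 0],
            "accel_y": session.accel[:, 1],
            "accel_z": session.accel[:, 2],
        }
    ).to_csv(out / "accel.csv", index=False, float_format="%.5f")
    pd.DataFrame(
        {
            "time_s": np.arange(session.ecg.shape[0]) / session.ecg_rate_hz,
            "ecg_mv": session.ecg,
        }
    ).to_csv(out / "ecg.csv", index=False, float_format="%.5f")
    write_gpx(out / "gps.gpx", session.gps,
              [s.waypoint_start for s in session.config.sections])
    session.test_scores.to_csv(out / "test_scores.csv", index=False)
    session.truth.to_csv(out / "truth_timeline.csv", index=False)
    pd.DataFrame(
        {"t_s": session.trajectory.t, "fatigue": session.trajectory.f}
    ).to_csv(out / "trajectory.csv", index=False)
    manifest = {
        "n_laps": session.config.n_laps,
        "seed": session.config.seed,
        "accel_rate_hz": session.accel_rate_hz,
        "ecg_rate_hz": session.ecg_rate_hz,
        "duration_s": int(session.duration_s),
    }
    manifest["hash"] = config_hash(manifest)
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return out


@dataclass
class LoadedSession:
    """Streams re-read from disk; satisfies the alignment contract."""

    accel: np.ndarray
    accel_rate_hz: float
    ecg: np.ndarray
    ecg_rate_hz: float
    gps: pd.DataFrame
    test_scores: pd.DataFrame
    truth: Optional[pd.DataFrame]
    trajectory: Optional[FatigueTrajectory]
    duration_s: int


def load_session(session_dir) -> LoadedSession:
    d = Path(session_dir)
    manifest = yaml.safe_load((d / "manifest.yaml").read_text())
    accel = pd.read_csv(d / "accel.csv")
    ecg = pd.read_csv(d / "ecg.csv")
    truth_path = d / "truth_timeline.csv"
    traj_path = d / "trajectory.csv"
    trajectory = None
    if traj_path.exists():
        tr = pd.read_csv(traj_path)
        trajectory = FatigueTrajectory(t=tr["t_s"].to_numpy(), f=tr["fatigue"].to_numpy())
    return LoadedSession(
        accel=accel[["accel_x", "accel_y", "accel_z"]].to_numpy(),
        accel_rate_hz=float(manifest["accel_rate_hz"]),
        ecg=ecg["ecg_mv"].to_numpy(),
        ecg_rate_hz=float(manifest["ecg_rate_hz"]),
        gps=read_gpx(d / "gps.gpx"),
        test_scores=pd.read_csv(d / "test_scores.csv"),
        truth=pd.read_csv(truth_path) if truth_path.exists() else None,
        trajectory=trajectory,
        duration_s=int(manifest["duration_s"]),
    )


def write_label_series(out_dir, label, preview_rows: int = 1000) -> None:
    """Binary label array plus a decimated CSV preview."""
    out = Path(out_dir)
    np.save(out / f"label_{label.method.lower()}.npy", label.values)
    step = max(1, label.values.size // preview_rows)
    pd.DataFrame(
        {
            "time_s": np.arange(0, label.values.size, step) / label.rate_hz,
            "value": label.values[::step],
        }
    ).to_csv(out / f"label_{label.method.lower()}_preview.csv", index=False)
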