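"""Deterministic signal conditioning.

Brings the raw streams onto a common 250 Hz grid (accelerometry up-sampled by
linear interpolation, ECG native), removes slow ECG baseline wander, and
provides per-channel min-max feature scaling onto [0, 1]:

    x_new = (x - x_min) / (x_max - x_min)

Scaling parameters are fit on the training partition by default and reused
for test windows; a ``fit_on="all"`` mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScalingParams",
    "AlignedStreams",
    "feature_scale",
    "inverse_feature_scale",
    "baseline_correct_ecg",
    "resample_linear",
    "align_session",
]

CHANNELS = ("accel_x", "accel_y", "accel_z", "ecg")
MODEL_RATE_HZ = 250.0


@dataclass(frozen=True)
class ScalingParams:
    """Per-channel min-max range used by feature scaling."""

    x_min: np.ndarray
    x_max: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "x_min", np.atleast_1d(np.asarray(self.x_min, float)))
        object.__setattr__(self, "x_max", np.atleast_1d(np.asarray(self.x_max, float)))
        if self.x_min.shape != self.x_max.shape:
            raise ValueError("x_min and x_max must have matching shapes")
        if np.any(self.x_max <= self.x_min):
            raise ValueError("feature scaling requires x_max > x_min per channel")

    @classmethod
    def fit(cls, x: np.ndarray) -> "ScalingParams":
        """Fit per-channel ranges; channels are the trailing axis."""
        x = np.asarray(x, float)
        flat = x.reshape(-1, x.shape[-1]) if x.ndim > 1 else x.reshape(-1, 1)
        return cls(x_min=flat.min(axis=0), x_max=flat.max(axis=0))


def feature_scale(x: np.ndarray, params: ScalingParams) -> np.ndarray:
    """Min-max scale onto [0, 1]; values from the fitting range land in [0, 1]."""
    x = np.asarray(x, float)
    return (x - params.x_min) / (params.x_max - params.x_min)


def inverse_feature_scale(x_new: np.ndarray, params: ScalingParams) -> np.ndarray:
    return np.asarray(x_new, float) * (params.x_max - params.x_min) + params.x_min


def resample_linear(x: np.ndarray, from_hz: float, to_hz: float) -> np.ndarray:
    """Linear-interpolation resampling; output length = round(n * to/from)."""
    if from_hz <= 0 or to_hz <= 0:
        raise ValueError("rates must be strictly positive")
    x = np.asarray(x, float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to resample")
    if from_hz == to_hz:
        return x.copy()
    n_out = int(round(n * to_hz / from_hz))
    t_in = np.arange(n) / from_hz
    t_out = np.arange(n_out) / to_hz
    if x.ndim == 1:
        return np.interp(t_out, t_in, x)
    return np.column_stack([np.interp(t_out, t_in, x[:, j]) for j in range(x.shape[1])])


def baseline_correct_ecg(
    ecg: np.ndarray,
    rate_hz: float = 250.0,
    w1_s: float = 0.2,
    w2_s: float = 0.6,
    stride: int = 10,
) -> np.ndarray:
    """Remove slow ECG baseline wander while preserving QRS amplitude.

    Two-stage running-median detrending: a short window (~200 ms) rejects the
    QRS complexes, a longer window (~600 ms) smooths over T waves; the
    resulting baseline estimate is subtracted.  The first-stage medians are
    evaluated on a strided grid and interpolated back — the baseline is by
    construction band-limited well below the stride rate, so this changes
    nothing but the cost.
    """
    x = np.asarray(ecg, float)
    k1 = max(3, int(round(w1_s * rate_hz)) | 1)
    if x.size < k1:
        raise ValueError(f"series shorter than the {w1_s:.1f} s correction window")
    half = k1 // 2
    padded = np.pad(x, half, mode="edge")
    windows = np.lib.stride_tricks.sliding_window_view(padded, k1)[::stride]
    centers = np.arange(windows.shape[0]) * stride
    stage1 = np.median(windows, axis=1)
    # second stage on the strided grid
    k2 = max(3, int(round(w2_s * rate_hz / stride)) | 1)
    if stage1.size >= k2:
        p2 = np.pad(stage1, k2 // 2, mode="edge")
        stage2 = np.median(np.lib.stride_tricks.sliding_window_view(p2, k2), axis=1)
    else:
        stage2 = stage1
    baseline = np.interp(np.arange(x.size), centers, stage2)
    return x - baseline


@dataclass
class AlignedStreams:
    """All channels on the shared 250 Hz model grid.

    ``data`` is (n, 4) with columns ``accel_x, accel_y, accel_z, ecg``; the
    accelerometer channels are linearly up-sampled from 100 Hz and the ECG is
    baseline-corrected in place.
    """

    data: np.ndarray
    rate_hz: float = MODEL_RATE_HZ
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[1] != len(CHANNELS):
            raise ValueError(f"expected (n, {len(CHANNELS)}) array")
        if np.isnan(self.data).any():
            raise ValueError("aligned streams must not contain missing values")

    @property
    def length_n(self) -> int:
        return self.data.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.length_n) / self.rate_hz

    def channel(self, name: str) -> np.ndarray:
        return self.data[:, CHANNELS.index(name)]


def align_session(session, correct_baseline: bool = True) -> AlignedStreams:
    """Build :class:`AlignedStreams` from a sensor session.

    Accepts any object with ``accel`` (n,3) at ``accel_rate_hz`` and ``ecg``
    (m,) at ``ecg_rate_hz`` attributes (a synthetic session or a real-data
    loader with the same contract); streams are trimmed to the common length.
    """
    accel_up = resample_linear(session.accel, session.accel_rate_hz, MODEL_RATE_HZ)
    ecg = np.asarray(session.ecg, float)
    if session.ecg_rate_hz != MODEL_RATE_HZ:
        ecg = resample_linear(ecg, session.ecg_rate_hz, MODEL_RATE_HZ)
    if correct_baseline:
        ecg = baseline_correct_ecg(ecg, MODEL_RATE_HZ)
    n = min(accel_up.shape[0], ecg.shape[0])
    data = np.column_stack([accel_up[:n], ecg[:n]])
    return AlignedStreams(data=data)
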