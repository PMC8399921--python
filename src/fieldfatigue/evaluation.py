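"""Rolling-window prediction smoothing and the MAE_k / RAE_k metrics.

A fatigue estimate is the unweighted mean of k consecutive window predictions
(default k = 200; at window width 128 samples and 250 Hz one estimate spans
200 * 128 / 250 = 102.4 s).  MAE_k is the mean and RAE_k the largest absolute
difference between the rolled predictions and the label; RAE is reported
because it bounds the error a user of the model would see on a future
prediction.  "Range of absolute error" is read as max|e| by default; a
``span`` mode (max - min of |e|) preserves the alternative reading.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .windowing import WindowedDataset, predict

__all__ = [
    "EvalResult",
    "rolling_average",
    "estimate_duration",
    "mae_rae",
    "evaluate_activity",
    "plot_predictions",
]

DEFAULT_K = 200


class InsufficientWindowsError(ValueError):
    """Raised when a series is shorter than the rolling length."""


def rolling_average(preds: np.ndarray, k: int) -> np.ndarray:
    """Sliding unweighted mean of length k, step 1 -> series of length n-k+1."""
    x = np.asarray(preds, float)
    if k < 1:
        raise ValueError("rolling length must be >= 1")
    if x.size < k:
        raise InsufficientWindowsError(
            f"insufficient windows: {x.size} < rolling length {k}"
        )
    c = np.concatenate([[0.0], np.cumsum(x)])
    return (c[k:] - c[:-k]) / k


def estimate_duration(k: int, width: int, rate_hz: float = 250.0) -> float:
    """Wall-clock span of one rolling estimate: k * W / rate seconds."""
    if k < 1 or width < 1 or rate_hz <= 0:
        raise ValueError("k, width and rate must be positive")
    return k * width / rate_hz


def mae_rae(rolled: np.ndarray, label: np.ndarray, rae_mode: str = "max") -> tuple[float, float]:
    """Mean and largest absolute difference between rolled predictions and label."""
    r = np.asarray(rolled, float)
    l = np.asarray(label, float)
    if r.shape != l.shape:
        raise ValueError("rolled predictions and labels must have equal length")
    if r.size == 0:
        raise ValueError("empty series")
    e = np.abs(r - l)
    if rae_mode == "max":
        rae = float(e.max())
    elif rae_mode == "span":
        rae = float(e.max() - e.min())
    else:
        raise ValueError(f"unknown rae mode {rae_mode!r}")
    return float(e.mean()), rae


@dataclass
class EvalResult:
    """Per-activity rolling-prediction metrics for one label method."""

    activity: str
    label_method: str
    k: int
    width: int
    mae_k: float
    rae_k: float
    n_windows: int
    excluded: bool = False

    @property
    def duration_s_per_estimate(self) -> float:
        return estimate_duration(self.k, self.width)


def evaluate_activity(
    model,
    ds_test: WindowedDataset,
    label_method: str,
    k: int = DEFAULT_K,
    rae_mode: str = "max",
) -> EvalResult:
    """Rolling-average evaluation of a trained model on one activity's test windows.

    Predictions are re-sorted into time order (the random split destroys it),
    rolled over k windows, and compared against the window label at the
    center of each k-block.  If fewer than k test windows exist the activity
    is recorded as excluded with NaN metrics rather than silently evaluated.
    """
    ordered = ds_test.time_ordered()
    n = len(ordered)
    if n < k:
        return EvalResult(
            activity=ds_test.activity, label_method=label_method, k=k,
            width=ds_test.width, mae_k=float("nan"), rae_k=float("nan"),
            n_windows=n, excluded=True,
        )
    preds = predict(model, ordered)
    rolled = rolling_average(preds, k)
    center = (k - 1) // 2
    labels = ordered.y[center: center + rolled.size]
    mae, rae = mae_rae(rolled, labels, rae_mode)
    return EvalResult(
        activity=ds_test.activity, label_method=label_method, k=k,
        width=ds_test.width, mae_k=mae, rae_k=rae, n_windows=n,
    )


def plot_predictions(
    ds_test: WindowedDataset,
    preds: np.ndarray,
    k: int,
    path,
    title: Optional[str] = None,
) -> None:
    """Time-ordered trace of label, raw predictions and rolled predictions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = ds_test.time_ordered()
    fig, ax = plt.subplots(figsize=(9, 4))
    xs = np.arange(len(ordered))
    ax.plot(xs, preds, color="0.8", lw=0.5, label="individual predictions")
    if len(ordered) >= k:
        rolled = rolling_average(preds, k)
        ax.plot(np.arange(rolled.size) + (k - 1) // 2, rolled, color="black",
                lw=1.5, label=f"rolling mean of {k}")
    ax.plot(xs, ordered.y, color="crimson", lw=1.0, label="label")
    ax.set_xlabel("window (time order)")
    ax.set_ylabel("normalized performance")
    ax.set_ylim(-0.05, 1.05)
    if title:
        ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
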