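"""Per-activity windowing into the (D, W, F) array, splitting and training.

All 250 Hz samples belonging to one composite activity are concatenated in
time order and cut into D = floor(N / W) consecutive non-overlapping windows
of width W; each window's label is the mean of the aligned 250 Hz label over
its source samples.  Windows may span concatenation seams between
non-adjacent segments of the same activity (which is what produces label
discontinuities in time-ordered prediction traces); a strict mode that breaks
windows at seams is available but off by default so the floor(N/W) window
accounting holds exactly.

The train/test split is a uniformly random window-level partition with test
fraction 0.33.  Random splitting of temporally adjacent windows leaks
autocorrelation between train and test; a blocked split mode is provided for
stricter evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .config import COMPOSITE_ACTIVITIES
from .labelling import ActivityTimeline, composite_activities
from .labels import FatigueLabelSeries
from .nn import CNN1DRegressor, CnnSpec, SWEEP_PRESET
from .prep import AlignedStreams, ScalingParams, feature_scale

__all__ = [
    "DATA_GROUPS",
    "DEFAULT_WIDTHS",
    "WindowedDataset",
    "SplitSpec",
    "window_count",
    "activity_sample_indices",
    "window_activity",
    "split_train_test",
    "train_cnn",
    "predict",
    "hyperparameter_sweep",
]

DATA_GROUPS = {"accel": slice(0, 3), "ecg": slice(3, 4), "combined": slice(0, 4)}
DEFAULT_WIDTHS = (64, 128, 256, 512)


def window_count(n_samples: int, width: int) -> int:
    """Number of non-overlapping windows: D = floor(N / W)."""
    if width < 1:
        raise ValueError("window width must be positive")
    return int(n_samples) // int(width)


@dataclass
class WindowedDataset:
    """(D, W, F) windows of one activity with aligned labels and metadata."""

    X: np.ndarray
    y: np.ndarray
    meta: pd.DataFrame  # order, start_sample, center_time_s
    activity: str
    width: int

    def __len__(self) -> int:
        return self.X.shape[0]

    def subset(self, indices: np.ndarray) -> "WindowedDataset":
        idx = np.asarray(indices, int)
        return WindowedDataset(
            X=self.X[idx], y=self.y[idx],
            meta=self.meta.iloc[idx].reset_index(drop=True),
            activity=self.activity, width=self.width,
        )

    def time_ordered(self) -> "WindowedDataset":
        return self.subset(np.argsort(self.meta["order"].to_numpy()))


@dataclass(frozen=True)
class SplitSpec:
    """Randomized window-level train/test split."""

    test_fraction: float = 0.33
    seed: int = 0
    blocked: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")


def activity_sample_indices(
    seconds: np.ndarray, rate_hz: float, n_total: int
) -> np.ndarray:
    """250 Hz sample indices covered by the given whole seconds, in time order."""
    r = int(round(rate_hz))
    sec = np.asarray(np.sort(seconds), int)
    idx = (sec[:, None] * r + np.arange(r)[None, :]).ravel()
    return idx[idx < n_total]


def _resolve_seconds(timeline, activity_name: str) -> np.ndarray:
    if isinstance(timeline, ActivityTimeline):
        return composite_activities(timeline).get(activity_name, np.empty(0, int))
    if isinstance(timeline, pd.DataFrame):  # ground-truth schedule
        return timeline.loc[timeline["activity"] == activity_name, "time_s"].to_numpy(int)
    return np.asarray(timeline, int)


def window_activity(
    streams: AlignedStreams,
    timeline: Union[ActivityTimeline, pd.DataFrame, np.ndarray],
    activity_name: str,
    width_w: int,
    label: FatigueLabelSeries,
    strict_seams: bool = False,
) -> WindowedDataset:
    """Cut one activity's concatenated samples into non-overlapping windows."""
    seconds = _resolve_seconds(timeline, activity_name)
    if seconds.size == 0:
        raise ValueError(f"activity {activity_name!r} absent from the timeline")
    idx = activity_sample_indices(seconds, streams.rate_hz, streams.length_n)
    n_label = np.asarray(label.values).shape[0]
    idx = idx[idx < n_label]
    if idx.size < width_w:
        raise ValueError(
            f"activity {activity_name!r} has {idx.size} samples, fewer than one "
            f"window of {width_w}"
        )
    if strict_seams:
        breaks = np.flatnonzero(np.diff(idx) != 1) + 1
        runs = np.split(idx, breaks)
    else:
        runs = [idx]

    xs, ys, orders, starts, centers = [], [], [], [], []
    order0 = 0
    for run in runs:
        d = window_count(run.size, width_w)
        if d == 0:
            continue
        take = run[: d * width_w]
        xs.append(streams.data[take].reshape(d, width_w, -1))
        ys.append(label.values[take].reshape(d, width_w).mean(axis=1))
        starts.append(take[::width_w])
        centers.append(take[width_w // 2:: width_w][:d] / streams.rate_hz)
        orders.append(order0 + np.arange(d))
        order0 += d
    if not xs:
        raise ValueError(f"activity {activity_name!r} yields no complete window")
    meta = pd.DataFrame(
        {
            "order": np.concatenate(orders),
            "start_sample": np.concatenate(starts),
            "center_time_s": np.concatenate(centers),
        }
    )
    return WindowedDataset(
        X=np.concatenate(xs), y=np.concatenate(ys), meta=meta,
        activity=activity_name, width=width_w,
    )


def split_train_test(
    ds: WindowedDataset, spec: SplitSpec = SplitSpec()
) -> tuple[WindowedDataset, WindowedDataset]:
    """Random window-level partition; |test| = round(fraction * D)."""
    d = len(ds)
    if d < 3:
        raise ValueError("need at least 3 windows to split")
    n_test = int(round(spec.test_fraction * d))
    n_test = min(max(n_test, 1), d - 1)
    rng = np.random.default_rng(spec.seed)
    if spec.blocked:
        # contiguous tail block: no temporally adjacent train/test neighbours
        cut = d - n_test
        test_idx = np.arange(cut, d)
        train_idx = np.arange(cut)
    else:
        perm = rng.permutation(d)
        test_idx = np.sort(perm[:n_test])
        train_idx = np.sort(perm[n_test:])
    return ds.subset(train_idx), ds.subset(test_idx)


def train_cnn(
    spec: CnnSpec,
    train: WindowedDataset,
    data_group: str = "combined",
    scaling: Optional[ScalingParams] = None,
) -> CNN1DRegressor:
    """Train the CNN on one activity's training windows.

    Channel selection follows the data group (3 accelerometer channels, the
    single ECG channel, or all 4 combined).  Feature-scaling parameters are
    fit on the training partition unless supplied, and stored on the model so
    test windows are scaled identically.
    """
    if len(train) == 0:
        raise ValueError("training set is empty")
    sl = DATA_GROUPS[data_group]
    x = train.X[:, :, sl]
    if scaling is None:
        scaling = ScalingParams.fit(x)
    model = CNN1DRegressor(window=train.width, n_channels=x.shape[2], spec=spec)
    model.scaling = scaling
    model.data_group = data_group
    model.fit(feature_scale(x, scaling), train.y)
    return model


def predict(model: CNN1DRegressor, ds: WindowedDataset) -> np.ndarray:
    """Per-window predictions, ordered by window start time."""
    if len(ds) == 0:
        return np.empty(0)
    ordered = ds.time_ordered()
    x = ordered.X[:, :, DATA_GROUPS[model.data_group]]
    return model.predict(feature_scale(x, model.scaling))


def hyperparameter_sweep(
    streams: AlignedStreams,
    timeline: Union[ActivityTimeline, pd.DataFrame],
    label: FatigueLabelSeries,
    spec: CnnSpec = SWEEP_PRESET,
    split: SplitSpec = SplitSpec(),
    data_groups: Sequence[str] = ("accel", "ecg", "combined"),
    activities: Sequence[str] = COMPOSITE_ACTIVITIES,
    widths: Sequence[int] = DEFAULT_WIDTHS,
    dry_run: bool = False,
) -> pd.DataFrame:
    """Run the data-group x activity x window-width experiment grid.

    One record per cell with sample and window counts and the test MAE; cells
    whose activity is absent or shorter than one window are recorded as
    skipped, never dropped.  ``dry_run`` enumerates the grid and the window
    accounting without training (test MAE left NaN).
    """
    rows = []
    for group in data_groups:
        for activity in activities:
            for w in widths:
                try:
                    ds = window_activity(streams, timeline, activity, w, label)
                except ValueError as exc:
                    rows.append((group, activity, w, 0, 0, np.nan, f"skipped: {exc}"))
                    continue
                n_samples = len(ds) * w
                if dry_run:
                    rows.append((group, activity, w, n_samples, len(ds), np.nan, "ok"))
                    continue
                try:
                    train, test = split_train_test(ds, split)
                except ValueError as exc:
                    rows.append((group, activity, w, n_samples, len(ds), np.nan,
                                 f"skipped: {exc}"))
                    continue
                model = train_cnn(spec, train, data_group=group)
                preds = predict(model, test)
                mae = float(np.mean(np.abs(preds - test.time_ordered().y)))
                rows.append((group, activity, w, n_samples, len(ds), mae, "ok"))
    return pd.DataFrame(
        rows,
        columns=["data_group", "activity", "width", "n_samples", "n_windows",
                 "test_mae", "status"],
    )
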