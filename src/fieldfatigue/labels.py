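"""Continuous fatigue labels from sparse performance-test scores.

Scores are min-max normalized over the protocol (1 = freshest observed state,
0 = most degraded) and up-sampled to the 250 Hz model grid by one of two
constructions:

* **LTLF** (long-term linear fit): ordinary least squares line through the
  normalized (time, score) observations, clipped to [0, 1] — appropriate when
  the protocol load is constant over time.
* **ITI** (inter-test interpolation): piecewise-linear interpolation between
  consecutive observations, constant beyond the ends — retains short-term
  fatigue and recovery, as needed for unstructured field loads.

The default label source is the dominant-hand finger-tap test, the most
protocol-sensitive assessment in the battery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestSeries",
    "FatigueLabelSeries",
    "normalize_scores",
    "build_ltlf",
    "build_iti",
    "sensitivity_r2",
    "label_from_scores",
]

DEFAULT_LABEL_SOURCE = "ftt_dominant"
LABEL_RATE_HZ = 250.0


@dataclass
class TestSeries:
    """Observations of one performance test over the session."""

    test_name: str
    times_s: np.ndarray
    scores: np.ndarray
    phases: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, float)
        self.scores = np.asarray(self.scores, float)
        if self.times_s.shape != self.scores.shape or self.times_s.ndim != 1:
            raise ValueError("times and scores must be matching 1-D arrays")
        if self.times_s.size < 2:
            raise ValueError("a test series needs at least 2 observations")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("observation times must be strictly increasing")

    @classmethod
    def from_table(cls, table: pd.DataFrame, test_name: str) -> "TestSeries":
        sub = table[table["test_name"] == test_name].sort_values("time_s")
        if sub.empty:
            raise KeyError(f"no observations for test {test_name!r}")
        return cls(
            test_name=test_name,
            times_s=sub["time_s"].to_numpy(float),
            scores=sub["score"].to_numpy(float),
            phases=sub["phase"].to_numpy(object) if "phase" in sub else None,
        )


@dataclass
class FatigueLabelSeries:
    """250 Hz continuous label in [0, 1] over the session."""

    method: str                # "LTLF" | "ITI"
    values: np.ndarray
    source_test: str = DEFAULT_LABEL_SOURCE
    rate_hz: float = LABEL_RATE_HZ

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("label values must lie in [0, 1]")


def normalize_scores(scores: np.ndarray) -> np.ndarray:
    """Min-max scale a score series over its own observations onto [0, 1]."""
    s = np.asarray(scores, float)
    lo, hi = s.min(), s.max()
    if hi <= lo:
        raise ValueError("cannot normalize a constant score series")
    return (s - lo) / (hi - lo)


def _label_grid(session_span_s: float, rate_hz: float) -> np.ndarray:
    n = int(round(session_span_s * rate_hz))
    return np.arange(n) / rate_hz


def build_ltlf(
    series: TestSeries, session_span_s: float, rate_hz: float = LABEL_RATE_HZ
) -> FatigueLabelSeries:
    """Long-term linear fit: OLS line through normalized scores, clipped to [0, 1]."""
    if np.ptp(series.times_s) <= 0:
        raise ValueError("degenerate time spread")
    y = normalize_scores(series.scores)
    slope, intercept = np.polyfit(series.times_s, y, 1)
    t = _label_grid(session_span_s, rate_hz)
    vals = np.clip(intercept + slope * t, 0.0, 1.0)
    return FatigueLabelSeries(method="LTLF", values=vals, source_test=series.test_name,
                              rate_hz=rate_hz)


def build_iti(
    series: TestSeries, session_span_s: float, rate_hz: float = LABEL_RATE_HZ
) -> FatigueLabelSeries:
    """Inter-test interpolation: piecewise-linear through every normalized
    observation, constant extrapolation before the first / after the last."""
    y = normalize_scores(series.scores)
    t = _label_grid(session_span_s, rate_hz)
    vals = np.interp(t, series.times_s, y)
    return FatigueLabelSeries(method="ITI", values=vals, source_test=series.test_name,
                              rate_hz=rate_hz)


def label_from_scores(
    table: pd.DataFrame,
    session_span_s: float,
    method: str = "LTLF",
    source_test: str = DEFAULT_LABEL_SOURCE,
    rate_hz: float = LABEL_RATE_HZ,
) -> FatigueLabelSeries:
    """Convenience: build a label series straight from the score table."""
    series = TestSeries.from_table(table, source_test)
    if method.upper() == "LTLF":
        return build_ltlf(series, session_span_s, rate_hz)
    if method.upper() == "ITI":
        return build_iti(series, session_span_s, rate_hz)
    raise ValueError(f"unknown label method {method!r}")


def sensitivity_r2(
    series: TestSeries,
    subset: str = "all",
    remove_outliers: bool = False,
    studentized_threshold: float = 3.0,
) -> float:
    """Squared Pearson correlation of score vs time: the test's sensitivity
    to the protocol load.

    ``subset`` restricts to observations tagged ``post_physical`` or
    ``post_cognitive``.  ``remove_outliers`` drops points whose externally
    studentized OLS residual exceeds the threshold (a reproducible proxy for
    manual outlier screening).
    """
    t, s = series.times_s, series.scores
    if subset != "all":
        if series.phases is None:
            raise ValueError("series carries no phase tags")
        mask = series.phases == subset
        t, s = t[mask], s[mask]
    if remove_outliers and t.size >= 4:
        keep = _studentized_keep(t, s, studentized_threshold)
        t, s = t[keep], s[keep]
    if t.size < 3:
        raise ValueError("subset leaves fewer than 3 observations")
    r = stats.pearsonr(t, s).statistic
    return float(r * r)


def _studentized_keep(t: np.ndarray, s: np.ndarray, threshold: float) -> np.ndarray:
    slope, intercept = np.polyfit(t, s, 1)
    resid = s - (intercept + slope * t)
    n = t.size
    h = 1.0 / n + (t - t.mean()) ** 2 / np.sum((t - t.mean()) ** 2)
    dof = n - 3
    if dof <= 0:
        return np.ones(n, dtype=bool)
    sse = np.sum(resid**2)
    s2_i = (sse - resid**2 / (1 - h)) / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        ext = resid / np.sqrt(np.maximum(s2_i * (1 - h), 1e-30))
    return np.abs(ext) <= threshold
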