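"""Forced-walking-task motion pipeline: loss-of-movement (LOM) scoring.

Stages, applied in order:

1. zero-phase 5th-order Butterworth band-pass (0.5-20 Hz) of the 3-axis
   accelerometer to strip the gravity/DC component,
2. instantaneous activity as the per-sample RMS over the three filtered axes
   (video mode: the per-frame displaced-pixel count is used directly),
3. a windowed activity index, mean x STD over 4 s windows with 50% overlap
   (sustained activity times its variability),
4. affine normalization so complete cessation maps near 0 and the 10 min
   pre-injection walking baseline averages exactly 1,
5. state classification: windows below the lower bound of the baseline's 95%
   band for >= 60 s are non-walking; non-walking stretches held below 0.25
   for >= 30 s are LOM,
6. summary metrics: latency to and duration of the first LOM after injection,
   and total LOM time over a 60 min horizon.

Because the normalization is affine in the raw index, every stage downstream
of it is invariant to a positive gain applied to the raw motion trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal as sps

from .io_formats import MotionSignal

__all__ = [
    "ActivityIndexSeries",
    "LocomotorStates",
    "LomMetrics",
    "filter_accelerometer",
    "instantaneous_activity",
    "video_frame_activity",
    "windowed_index",
    "normalize_index",
    "classify_states",
    "lom_metrics",
]

WINDOW_S = 4.0
STEP_S = 2.0


@dataclass
class ActivityIndexSeries:
    """Windowed motion index over time.

    ``raw_index[w]`` is mean x STD of instantaneous activity in window ``w``;
    ``norm_index`` is its affine normalization (present only after
    :func:`normalize_index`). ``window_starts_s`` are the window left edges;
    windows are ``window_s`` long with step ``step_s``.
    """

    window_starts_s: np.ndarray
    raw_index: np.ndarray
    window_s: float = WINDOW_S
    step_s: float = STEP_S
    norm_index: np.ndarray | None = None
    baseline_interval_s: tuple[float, float] | None = None
    floor: float | None = None
    baseline_mean_raw: float | None = None

    @property
    def window_centers_s(self) -> np.ndarray:
        return self.window_starts_s + self.window_s / 2.0

    @property
    def n_windows(self) -> int:
        return int(self.raw_index.size)

    def baseline_window_mask(self) -> np.ndarray:
        """Windows lying entirely inside the baseline interval."""
        if self.baseline_interval_s is None:
            raise ValueError("no baseline interval set")
        b0, b1 = self.baseline_interval_s
        return (self.window_starts_s >= b0) & (
            self.window_starts_s + self.window_s <= b1
        )


@dataclass
class LocomotorStates:
    """Per-window locomotor labels and the episode list they tile."""

    window_starts_s: np.ndarray
    labels: np.ndarray  # {"walking", "nonwalking", "LOM"} per window
    step_s: float
    episodes: pd.DataFrame  # columns start_s, end_s, label
    nonwalk_threshold: float
    lom_threshold: float

    def episodes_of(self, label: str) -> pd.DataFrame:
        return self.episodes[self.episodes["label"] == label].reset_index(drop=True)


@dataclass
class LomMetrics:
    """First-LOM latency/duration and total LOM time; NaN means undefined."""

    latency_fLOM_s: float = math.nan
    duration_fLOM_s: float = math.nan
    total_LOM_s: float = math.nan

    def to_frame_row(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "latency_fLOM_s": self.latency_fLOM_s,
                    "duration_fLOM_s": self.duration_fLOM_s,
                    "total_LOM_s": self.total_LOM_s,
                }
            ]
        )


def filter_accelerometer(
    signal: MotionSignal,
    low_hz: float = 0.5,
    high_hz: float = 20.0,
    order: int = 5,
) -> MotionSignal:
    """Zero-phase Butterworth band-pass of a 3-axis accelerometer signal.

    Removes the DC/gravity component and out-of-band drift. Forward-backward
    filtering makes the response zero-phase (no group delay).
    """
    if signal.mode != "accelerometer":
        raise ValueError("filter_accelerometer expects a 3-channel accelerometer signal")
    if signal.sample_rate_hz <= 2 * high_hz:
        raise ValueError(
            f"sample rate {signal.sample_rate_hz:g} Hz too low for a "
            f"{high_hz:g} Hz cutoff; check the recording rate"
        )
    sos = sps.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=signal.sample_rate_hz,
        output="sos",
    )
    filtered = sps.sosfiltfilt(sos, signal.channels, axis=1)
    return MotionSignal(signal.sample_rate_hz, filtered, t0_s=signal.t0_s,
                        validate=False)


def instantaneous_activity(signal: MotionSignal) -> np.ndarray:
    """Instantaneous activity: RMS over the three filtered axes per sample.

    Video mode passes the (already non-negative) per-frame motion scalar
    through unchanged.
    """
    if signal.mode == "accelerometer":
        if signal.channels.shape[0] != 3:
            raise ValueError("accelerometer mode requires exactly 3 channels")
        return np.sqrt(np.mean(signal.channels**2, axis=0))
    return np.maximum(signal.channels[0], 0.0)


def video_frame_activity(
    frames: np.ndarray, diff_threshold: float = 0.5
) -> np.ndarray:
    """Per-frame motion scalar from a video stack of shape (T, H, W).

    Frame-by-frame absolute intensity difference, 3x3 median filtering, then
    the count of displaced pixels (median-filtered difference above
    threshold). Isolated single-pixel flickers are removed by the median
    kernel. The first frame has no predecessor and scores 0.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must have shape (T, H, W)")
    out = np.zeros(frames.shape[0])
    for i in range(1, frames.shape[0]):
        diff = np.abs(frames[i] - frames[i - 1])
        med = ndimage.median_filter(diff, size=3)
        out[i] = float(np.count_nonzero(med > diff_threshold))
    return out


def windowed_index(
    activity: np.ndarray,
    sample_rate_hz: float,
    t0_s: float = 0.0,
    window_s: float = WINDOW_S,
    step_s: float = STEP_S,
) -> ActivityIndexSeries:
    """Mean x STD of instantaneous activity in overlapping windows.

    Windows are anchored at ``t0_s`` and advance by ``step_s`` (50% overlap at
    the defaults); the raw index of a window is the product of its mean and
    its standard deviation, i.e. sustained activity times variability.
    """
    activity = np.asarray(activity, dtype=float)
    wlen = int(round(window_s * sample_rate_hz))
    step = int(round(step_s * sample_rate_hz))
    if activity.size < wlen:
        raise ValueError(
            f"series of {activity.size / sample_rate_hz:g} s is shorter than "
            f"one {window_s:g} s window"
        )
    n_win = (activity.size - wlen) // step + 1
    idx = np.arange(n_win)[:, None] * step + np.arange(wlen)[None, :]
    w = activity[idx]
    raw = w.mean(axis=1) * w.std(axis=1)
    starts = t0_s + np.arange(n_win) * step_s
    return ActivityIndexSeries(starts, raw, window_s=window_s, step_s=step_s)


def normalize_index(
    series: ActivityIndexSeries,
    baseline_interval_s: tuple[float, float],
    floor_percentile: float = 1.0,
) -> ActivityIndexSeries:
    """Affine normalization of the raw index.

    The cessation floor is a low percentile of the raw index over the whole
    recording (robust even when no true zero-motion segment exists); the
    baseline scale is the mean raw index over windows fully inside the
    pre-injection walking interval. After mapping, the baseline averages
    exactly 1 and values at the floor map to 0; results are clipped at 0.
    """
    b0, b1 = baseline_interval_s
    if b1 - b0 < 60.0:
        raise ValueError("baseline interval must be at least 60 s")
    out = ActivityIndexSeries(
        series.window_starts_s.copy(),
        series.raw_index.copy(),
        window_s=series.window_s,
        step_s=series.step_s,
        baseline_interval_s=(float(b0), float(b1)),
    )
    mask = out.baseline_window_mask()
    if not mask.any():
        raise ValueError("no complete windows inside the baseline interval")
    floor = float(np.percentile(out.raw_index, floor_percentile))
    bmean = float(out.raw_index[mask].mean())
    if bmean <= floor:
        raise ValueError(
            "degenerate baseline: mean baseline index does not exceed the "
            "cessation floor"
        )
    out.floor = floor
    out.baseline_mean_raw = bmean
    out.norm_index = np.clip((out.raw_index - floor) / (bmean - floor), 0.0, None)
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open index ranges [i0, i1)."""
    out = []
    i = 0
    n = mask.size
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def classify_states(
    series: ActivityIndexSeries,
    injection_time_s: float,
    lom_threshold: float = 0.25,
    nonwalk_min_s: float = 60.0,
    lom_min_s: float = 30.0,
    baseline_lower_percentile: float = 2.5,
) -> LocomotorStates:
    """Window-wise walking / non-walking / LOM classification.

    Windows are walking by default. Maximal runs of windows whose normalized
    index falls below the empirical lower bound of the baseline's 95% band
    (the 2.5th percentile of baseline window values) lasting at least
    ``nonwalk_min_s`` become non-walking; within those, maximal runs held
    below ``lom_threshold`` for at least ``lom_min_s`` become LOM. Each
    window owns one step-length slot, so episode boundaries snap to the 2 s
    window grid.
    """
    if series.norm_index is None:
        raise ValueError("series must be normalized first")
    t_first = series.window_starts_s[0]
    t_last = series.window_starts_s[-1] + series.step_s
    if not (t_first <= injection_time_s <= t_last):
        raise ValueError(
            f"injection time {injection_time_s:g} s outside classified span "
            f"[{t_first:g}, {t_last:g}] s"
        )
    norm = series.norm_index
    base_vals = norm[series.baseline_window_mask()]
    nonwalk_thr = float(np.percentile(base_vals, baseline_lower_percentile))

    labels = np.full(norm.size, "walking", dtype=object)
    need_nw = int(math.ceil(nonwalk_min_s / series.step_s))
    need_lom = int(math.ceil(lom_min_s / series.step_s))
    for i0, i1 in _runs(norm < nonwalk_thr):
        if i1 - i0 >= need_nw:
            labels[i0:i1] = "nonwalking"
            sub = norm[i0:i1] < lom_threshold
            for j0, j1 in _runs(sub):
                if j1 - j0 >= need_lom:
                    labels[i0 + j0 : i0 + j1] = "LOM"

    starts = series.window_starts_s
    rows = []
    i = 0
    while i < labels.size:
        j = i
        while j < labels.size and labels[j] == labels[i]:
            j += 1
        rows.append(
            {
                "start_s": starts[i],
                "end_s": starts[j - 1] + series.step_s,
                "label": labels[i],
            }
        )
        i = j
    episodes = pd.DataFrame(rows, columns=["start_s", "end_s", "label"])
    return LocomotorStates(
        window_starts_s=starts,
        labels=labels,
        step_s=series.step_s,
        episodes=episodes,
        nonwalk_threshold=nonwalk_thr,
        lom_threshold=lom_threshold,
    )


def lom_metrics(
    states: LocomotorStates,
    injection_time_s: float,
    horizon_s: float = 3600.0,
) -> LomMetrics:
    """First-LOM latency and duration, and total LOM time within the horizon.

    The first LOM is the earliest LOM episode with onset at or after the
    injection; total LOM time clips episodes to the half-open horizon
    ``[injection, injection + horizon)``. All three metrics are NaN when no
    LOM occurs.
    """
    lom = states.episodes_of("LOM")
    lom = lom[lom["start_s"] >= injection_time_s]
    if lom.empty:
        return LomMetrics()
    first = lom.iloc[0]
    h0, h1 = injection_time_s, injection_time_s + horizon_s
    clipped = np.clip(lom["end_s"], h0, h1) - np.clip(lom["start_s"], h0, h1)
    return LomMetrics(
        latency_fLOM_s=float(first["start_s"] - injection_time_s),
        duration_fLOM_s=float(first["end_s"] - first["start_s"]),
        total_LOM_s=float(np.sum(np.maximum(clipped, 0.0))),
    )
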