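"""Single-unit firing-mode analytics.

Autocorrelograms and the two burst indices computed from them, detection of
low-threshold-burst events (clusters of short inter-spike intervals preceded
by silence), per-brain-state tonic/burst firing metrics, regular- vs
narrow-spiking classification by spike width, wake-referenced Z-scoring of
state firing, and peristimulus response statistics around stimulation pulses.

Conventions: the autocorrelogram is one-sided at 1 ms resolution with the
zero-lag self-pairs excluded and counts left unnormalized (both indices are
ratios of counts, so any normalization cancels). Burst criteria follow the
analysis windows used throughout: intra-burst inter-spike intervals of at
most 10 ms, at least 2 spikes, and at least 50 ms of silence before the
first spike.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import EpochSet, PulseProtocol, SpikeTrain

__all__ = [
    "Autocorrelogram",
    "BurstSet",
    "ZClassification",
    "PeristimulusResult",
    "autocorrelogram",
    "burst_index",
    "bursting_ratio_index",
    "detect_bursts",
    "state_firing_metrics",
    "classify_cell_type",
    "zscore_vs_wake",
    "peristimulus_histogram",
]

Z_THRESHOLD = 1.96  # two-sided p = 0.05 bound in SD units

RS_NS_WIDTH_US = 250.0


@dataclass
class Autocorrelogram:
    """One-sided spike autocorrelogram at 1 ms resolution.

    ``counts[k-1]`` is the number of ordered spike pairs whose lag falls in
    the bin centered at ``k`` ms (edges ``[k-0.5, k+0.5)``), for
    ``k = 1..max_lag_ms``; zero-lag self-pairs are excluded.
    """

    counts: np.ndarray
    bin_ms: float = 1.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("autocorrelogram counts must be non-negative")

    @property
    def max_lag_ms(self) -> float:
        return self.counts.size * self.bin_ms

    @property
    def lags_ms(self) -> np.ndarray:
        return (np.arange(self.counts.size) + 1) * self.bin_ms


@dataclass
class BurstSet:
    """Burst events of one unit, partitioning its spikes into burst vs tonic."""

    onsets_s: np.ndarray
    spike_counts: np.ndarray
    burst_spike_times_s: list[np.ndarray]
    tonic_spike_times_s: np.ndarray
    isi_max_ms: float
    silence_min_ms: float
    min_spikes: int

    @property
    def n_bursts(self) -> int:
        return int(self.onsets_s.size)

    @property
    def n_burst_spikes(self) -> int:
        return int(np.sum(self.spike_counts)) if self.spike_counts.size else 0

    def intra_burst_isis_s(self) -> list[np.ndarray]:
        return [np.diff(b) for b in self.burst_spike_times_s]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_s": self.onsets_s,
                "n_spikes": self.spike_counts,
                "duration_s": [
                    b[-1] - b[0] for b in self.burst_spike_times_s
                ] if self.n_bursts else [],
            }
        )


@dataclass(frozen=True)
class ZClassification:
    """Wake-referenced Z-score of a target state's firing with its label."""

    z: float
    label: str  # increase | no_change | decrease | undefined
    wake_mean_hz: float = math.nan
    wake_sd_hz: float = math.nan
    target_rate_hz: float = math.nan


@dataclass
class PeristimulusResult:
    """Spike-latency histogram around pulse onsets plus fidelity statistics."""

    bin_edges_ms: np.ndarray
    counts: np.ndarray
    fidelity: float
    latency_ms: float  # median first-spike latency; NaN if no responses
    jitter_ms: float  # SD of first-spike latency; NaN if no responses
    n_pulses: int


def autocorrelogram(train: SpikeTrain, max_lag_ms: float = 100.0) -> Autocorrelogram:
    """Histogram of positive lags between ordered spike pairs (1 ms bins)."""
    t_ms = train.spike_times_s * 1000.0
    if t_ms.size < 2:
        raise ValueError("autocorrelogram requires at least 2 spikes")
    max_lag = float(max_lag_ms)
    hi_edge = max_lag + 0.5
    lags = []
    right = np.searchsorted(t_ms, t_ms + hi_edge, side="left")
    for i in range(t_ms.size - 1):
        if right[i] > i + 1:
            lags.append(t_ms[i + 1 : right[i]] - t_ms[i])
    all_lags = np.concatenate(lags) if lags else np.empty(0)
    edges = np.arange(0.5, hi_edge + 1e-9, 1.0)
    counts, _ = np.histogram(all_lags, bins=edges)
    return Autocorrelogram(counts.astype(int))


def _bin_slice(acg: Autocorrelogram, lo_ms: float, hi_ms: float) -> np.ndarray:
    """Counts of bins with centers in [lo_ms, hi_ms] (inclusive)."""
    centers = acg.lags_ms
    return acg.counts[(centers >= lo_ms) & (centers <= hi_ms)]


def burst_index(acg: Autocorrelogram) -> float:
    """Normalized difference between the early peak and the 40-50 ms baseline.

    The peak is the maximum single-bin count at lags 1-10 ms (earliest lag on
    ties) and the baseline is the mean count over the 40-50 ms bins. The
    positive amplitude (peak - baseline) is normalized to the peak and the
    negative amplitude to the baseline, so the index lies in [-1, 1]; a flat
    autocorrelogram scores 0.
    """
    if acg.max_lag_ms < 50:
        raise ValueError("burst index needs an autocorrelogram covering >= 50 ms")
    peak = float(np.max(_bin_slice(acg, 1, 10)))
    baseline = float(np.mean(_bin_slice(acg, 40, 50)))
    amp = peak - baseline
    if peak == 0 and baseline == 0:
        warnings.warn("degenerate autocorrelogram: no counts in either window")
        return 0.0
    if amp > 0:
        return amp / peak
    if amp < 0:
        return amp / baseline
    return 0.0


def bursting_ratio_index(acg: Autocorrelogram) -> float:
    """Ratio of autocorrelogram counts at lags < 10 ms to counts at lags > 50 ms.

    Returns ``inf`` (with a diagnostic warning) when there are short-lag
    counts but none beyond 50 ms.
    """
    if acg.max_lag_ms <= 50:
        raise ValueError("ratio index needs an autocorrelogram covering > 50 ms")
    short = float(np.sum(acg.counts[acg.lags_ms < 10]))
    long = float(np.sum(acg.counts[acg.lags_ms > 50]))
    if long == 0:
        warnings.warn("no counts beyond 50 ms; ratio index undefined (inf)")
        return math.inf if short > 0 else 0.0
    return short / long


def detect_bursts(
    train: SpikeTrain,
    isi_max_ms: float = 10.0,
    silence_min_ms: float = 50.0,
    min_spikes: int = 2,
) -> BurstSet:
    """Detect low-threshold-burst events in a sorted spike train.

    A burst is a maximal run of at least ``min_spikes`` spikes whose
    consecutive inter-spike intervals are all at most ``isi_max_ms`` and whose
    first spike is preceded by at least ``silence_min_ms`` of silence (the
    first spike of the train trivially satisfies the silence condition). All
    spikes outside bursts are tonic; the partition is exact.
    """
    t = train.spike_times_s
    isi_max = isi_max_ms / 1000.0
    silence = silence_min_ms / 1000.0
    onsets: list[float] = []
    spikes: list[np.ndarray] = []
    in_burst = np.zeros(t.size, dtype=bool)
    i = 0
    while i < t.size:
        j = i
        while j + 1 < t.size and t[j + 1] - t[j] <= isi_max:
            j += 1
        run_len = j - i + 1
        quiet_before = i == 0 or (t[i] - t[i - 1]) >= silence
        if run_len >= min_spikes and quiet_before:
            onsets.append(t[i])
            spikes.append(t[i : j + 1].copy())
            in_burst[i : j + 1] = True
        i = j + 1
    return BurstSet(
        onsets_s=np.asarray(onsets),
        spike_counts=np.asarray([s.size for s in spikes], dtype=int),
        burst_spike_times_s=spikes,
        tonic_spike_times_s=t[~in_burst],
        isi_max_ms=isi_max_ms,
        silence_min_ms=silence_min_ms,
        min_spikes=min_spikes,
    )


def _count_in_intervals(times: np.ndarray, intervals: np.ndarray) -> int:
    if times.size == 0 or intervals.size == 0:
        return 0
    lo = np.searchsorted(times, intervals[:, 0], side="left")
    hi = np.searchsorted(times, intervals[:, 1], side="left")
    return int(np.sum(hi - lo))


def state_firing_metrics(
    train: SpikeTrain,
    bursts: BurstSet,
    epochs: EpochSet,
    bursting_events_per_10min: float = 1.0,
    strict: bool = True,
) -> pd.DataFrame:
    """Per-state tonic/burst firing metrics for one unit.

    For every state label present in the epoch set, rates use the summed
    occupied duration of that state as the denominator: the tonic rate counts
    non-burst spikes per second, the burst spike rate counts spikes inside
    bursts per second, and the burst event rate counts burst onsets per
    minute (an event belongs to the epoch containing its onset). A unit is
    flagged bursting in a state when its burst events per 10 minutes exceed
    ``bursting_events_per_10min`` (strictly, by default). States with zero
    occupied time are omitted rather than reported as 0.
    """
    burst_spike_times = (
        np.sort(np.concatenate(bursts.burst_spike_times_s))
        if bursts.n_bursts
        else np.empty(0)
    )
    rows = []
    for lab in epochs.present_labels:
        iv = epochs.intervals(lab)
        dur = float(np.sum(iv[:, 1] - iv[:, 0]))
        if dur <= 0:
            continue
        n_tonic = _count_in_intervals(bursts.tonic_spike_times_s, iv)
        n_bspk = _count_in_intervals(burst_spike_times, iv)
        n_events = _count_in_intervals(bursts.onsets_s, iv)
        tonic_rate = n_tonic / dur
        bspk_rate = n_bspk / dur
        ev_per_min = n_events / dur * 60.0
        total = tonic_rate + bspk_rate
        ev_per_10min = ev_per_min * 10.0
        rows.append(
            {
                "unit_id": train.unit_id,
                "state": lab,
                "duration_s": dur,
                "total_rate_hz": total,
                "tonic_rate_hz": tonic_rate,
                "burst_spike_rate_hz": bspk_rate,
                "burst_event_rate_per_min": ev_per_min,
                "burst_to_total_ratio": bspk_rate / total if total > 0 else 0.0,
                "is_bursting": (
                    ev_per_10min > bursting_events_per_10min
                    if strict
                    else ev_per_10min >= bursting_events_per_10min
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "unit_id", "state", "duration_s", "total_rate_hz", "tonic_rate_hz",
            "burst_spike_rate_hz", "burst_event_rate_per_min",
            "burst_to_total_ratio", "is_bursting",
        ],
    )


def classify_cell_type(
    p2v_width_us: float | None, burst_capable: bool | None = None
) -> str:
    """Regular-spiking vs narrow-spiking by peak-to-valley spike width.

    RS if and only if the width strictly exceeds 250 us; a width of exactly
    250 us is NS. Returns ``"unclassified"`` when the width is missing. The
    ``burst_capable`` flag is carried for reporting but does not override the
    width rule.
    """
    if p2v_width_us is None or (
        isinstance(p2v_width_us, float) and math.isnan(p2v_width_us)
    ):
        return "unclassified"
    if not p2v_width_us > 0:
        raise ValueError("spike width must be positive")
    return "RS" if p2v_width_us > RS_NS_WIDTH_US else "NS"


def zscore_vs_wake(
    train: SpikeTrain,
    wake_epochs: EpochSet,
    target_epochs: EpochSet,
    bin_s: float = 10.0,
) -> ZClassification:
    """Z-score a target state's firing rate against binned home-cage wake firing.

    Wake firing is discretized into complete ``bin_s`` bins within the wake
    epochs; their mean and SD define the reference distribution. The target
    rate is total target-state spikes over total target time. Labels use the
    two-sided p = 0.05 bounds: increase for z > 1.96, decrease for z < -1.96,
    no change otherwise; an SD of zero yields an ``undefined`` sentinel.
    """
    rates = []
    for s0, s1 in np.column_stack([wake_epochs.starts_s, wake_epochs.ends_s]):
        n_bins = int((s1 - s0) // bin_s)
        for k in range(n_bins):
            b0 = s0 + k * bin_s
            rates.append(train.count_in(b0, b0 + bin_s) / bin_s)
    rates = np.asarray(rates)
    if rates.size < 10:
        raise ValueError(
            f"wake occupancy of {rates.size} bins < 10 required for Z-scoring"
        )
    mu = float(rates.mean())
    sd = float(rates.std(ddof=1))
    iv = np.column_stack([target_epochs.starts_s, target_epochs.ends_s])
    tdur = float(np.sum(iv[:, 1] - iv[:, 0]))
    target_rate = _count_in_intervals(train.spike_times_s, iv) / tdur
    if sd == 0:
        warnings.warn("wake firing has zero variance; Z-score undefined")
        return ZClassification(math.nan, "undefined", mu, sd, target_rate)
    z = (target_rate - mu) / sd
    if z > Z_THRESHOLD:
        label = "increase"
    elif z < -Z_THRESHOLD:
        label = "decrease"
    else:
        label = "no_change"
    return ZClassification(float(z), label, mu, sd, target_rate)


def peristimulus_histogram(
    train: SpikeTrain,
    pulses: PulseProtocol,
    window_ms: float = 20.0,
    bin_ms: float = 1.0,
) -> PeristimulusResult:
    """Spike latencies around pulse onsets with response-fidelity statistics.

    The histogram covers ``[-window_ms, window_ms)`` at ``bin_ms`` resolution.
    Fidelity is the fraction of pulses with at least one spike in the
    post-onset window ``(0, window_ms]``; latency is the median and jitter the
    SD of the per-pulse first-spike latency over responsive pulses.
    """
    if pulses.n_pulses < 1:
        raise ValueError("need at least one pulse")
    if window_ms <= 0:
        raise ValueError("window must be positive")
    w = window_ms / 1000.0
    t = train.spike_times_s
    all_lat = []
    first_lat = []
    for onset in pulses.onsets_s:
        lo = np.searchsorted(t, onset - w, side="left")
        hi = np.searchsorted(t, onset + w, side="left")
        lat = (t[lo:hi] - onset) * 1000.0
        all_lat.append(lat)
        post = lat[(lat > 0) & (lat <= window_ms)]
        if post.size:
            first_lat.append(post[0])
    lats = np.concatenate(all_lat) if all_lat else np.empty(0)
    edges = np.arange(-window_ms, window_ms + 1e-9, bin_ms)
    counts, _ = np.histogram(lats, bins=edges)
    fidelity = len(first_lat) / pulses.n_pulses
    if first_lat:
        latency = float(np.median(first_lat))
        jitter = float(np.std(first_lat))
    else:
        latency = math.nan
        jitter = math.nan
    return PeristimulusResult(
        bin_edges_ms=edges,
        counts=counts,
        fidelity=float(fidelity),
        latency_ms=latency,
        jitter_ms=jitter,
        n_pulses=pulses.n_pulses,
    )
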