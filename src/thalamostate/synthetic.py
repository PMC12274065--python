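"""Synthetic spike trains, motion traces, and waveform-width fixtures.

The generators emulate the statistical structure the downstream analyses
assume — state-dependent tonic firing with low-threshold-burst events for
wild-type-like units and tonic-only firing for knockout-like units, and a
forced-walking motion trace with a walking baseline followed by planted
quiescent (loss-of-movement) episodes — so every stage of the pipeline is
testable against attached latent ground truth.

Tonic spikes are drawn as a dead-time renewal process: a Poisson stream
thinned by a minimum tonic inter-spike interval, with the driving rate
calibrated so the realized rate equals the requested one. The minimum ISI
reflects the defining feature of tonic-mode (and knockout) thalamic firing,
the absence of the short inter-spike intervals that constitute bursts; without
it, chance short ISIs in a Poisson stream would masquerade as burst events at
rates far above anything seen outside genuine burst mode. Burst onsets are
drawn the same way, with the dead time set to one pre-burst silence plus the
longest possible burst so that bursts never collide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_formats import EpochSet, MotionSignal, SpikeTrain

__all__ = [
    "StateSpikeParams",
    "SpikeGenParams",
    "SpikeTrainTruth",
    "MotionEpisode",
    "MotionGenParams",
    "MotionTruth",
    "gen_state_schedule",
    "gen_spike_train",
    "gen_motion_trace",
    "gen_waveform_widths",
    "default_wt_params",
    "default_ko_params",
]


@dataclass(frozen=True)
class StateSpikeParams:
    """Firing-mode parameters of one brain state."""

    tonic_rate_hz: float
    burst_event_rate_per_min: float

    def __post_init__(self) -> None:
        if self.tonic_rate_hz < 0 or self.burst_event_rate_per_min < 0:
            raise ValueError("rates must be non-negative")


#: Default wild-type per-state parameters. Burst event rates for wake, fLOM
#: and NREM are the study's reported group means (0.16, 0.79 and 5.76
#: events/min); walk mirrors wake and REM is set to a low intermediate value.
#: Tonic rates are free parameters chosen only to reproduce the qualitative
#: ordering walk ~ wake > REM > NREM of state-dependent thalamic firing.
DEFAULT_WT_STATES: Mapping[str, StateSpikeParams] = {
    "walk": StateSpikeParams(20.0, 0.16),
    "wake": StateSpikeParams(20.0, 0.16),
    "REM": StateSpikeParams(8.0, 0.5),
    "NREM": StateSpikeParams(3.0, 5.76),
    "fLOM": StateSpikeParams(5.0, 0.79),
    "LOM": StateSpikeParams(5.0, 0.79),
    "nonwalk": StateSpikeParams(20.0, 0.16),
}


@dataclass
class SpikeGenParams:
    """Generator settings shared across states.

    ``tonic_min_isi_ms`` is the dead time of the tonic renewal process; it
    must exceed the burst-detection short-ISI window (10 ms) so that tonic
    discharge carries no burst-like intervals, and stay below the shortest
    mean tonic ISI requested.
    """

    states: Mapping[str, StateSpikeParams] = field(
        default_factory=lambda: dict(DEFAULT_WT_STATES)
    )
    spikes_per_burst: tuple[int, int] = (2, 5)
    intra_burst_isi_ms: tuple[float, float] = (3.0, 5.0)
    pre_burst_silence_ms: float = 100.0
    refractory_ms: float = 1.0
    tonic_min_isi_ms: float = 20.0

    def __post_init__(self) -> None:
        lo, hi = self.intra_burst_isi_ms
        if not (0 < lo <= hi <= 10):
            raise ValueError("intra-burst ISI range must lie within (0, 10] ms")
        if self.spikes_per_burst[0] < 2 or self.spikes_per_burst[0] > self.spikes_per_burst[1]:
            raise ValueError("spikes_per_burst must be an increasing range with low >= 2")
        if self.pre_burst_silence_ms < 50:
            raise ValueError("pre_burst_silence_ms must be >= 50")
        if not self.refractory_ms > 0:
            raise ValueError("refractory_ms must be positive")
        if self.tonic_min_isi_ms <= 10:
            raise ValueError("tonic_min_isi_ms must exceed the 10 ms burst window")

    @property
    def max_burst_span_s(self) -> float:
        n_lo, n_hi = self.spikes_per_burst
        return (n_hi - 1) * self.intra_burst_isi_ms[1] / 1000.0


def default_wt_params() -> SpikeGenParams:
    return SpikeGenParams()


def default_ko_params() -> SpikeGenParams:
    """Knockout-like settings: burst event rate forced to zero in every state."""
    states = {
        lab: StateSpikeParams(p.tonic_rate_hz, 0.0)
        for lab, p in DEFAULT_WT_STATES.items()
    }
    return SpikeGenParams(states=states)


@dataclass
class SpikeTrainTruth:
    """Latent ground truth attached to a generated spike train."""

    burst_onsets_s: np.ndarray
    burst_spike_counts: np.ndarray
    genotype: str
    n_tonic_spikes: int

    @property
    def n_bursts(self) -> int:
        return int(self.burst_onsets_s.size)


def _dead_time_renewal(
    rng: np.random.Generator,
    rate_hz: float,
    dead_s: float,
    start_s: float,
    end_s: float,
    what: str = "event",
) -> np.ndarray:
    """Events of a Poisson stream thinned by a non-paralyzable dead time.

    The driving rate is calibrated (``lam = r / (1 - r * dead)``) so the
    realized steady-state rate equals ``rate_hz`` exactly. Raises when the
    requested rate cannot be honored under the dead time.
    """
    if rate_hz == 0 or end_s <= start_s:
        return np.empty(0)
    if rate_hz * dead_s >= 1.0:
        raise ValueError(
            f"{what} rate {rate_hz:g}/s cannot honor a {dead_s * 1e3:g} ms "
            "minimum interval"
        )
    lam = rate_hz / (1.0 - rate_hz * dead_s)
    out = []
    # first event: plain exponential waiting time (no dead time carried in)
    t = start_s + rng.exponential(1.0 / lam)
    while t < end_s:
        out.append(t)
        t += dead_s + rng.exponential(1.0 / lam)
    return np.asarray(out)


def gen_state_schedule(
    seed: int,
    total_s: float,
    state_menu: Sequence[str],
    mean_epoch_s: float = 120.0,
    min_epoch_s: float = 30.0,
) -> EpochSet:
    """Contiguous random tiling of ``[0, total_s)`` with labels from the menu.

    Epoch durations are uniform on ``[min_epoch_s, 2*mean_epoch_s -
    min_epoch_s]``; consecutive epochs never repeat a label when the menu has
    more than one entry. Reproducible for a fixed seed.
    """
    if total_s <= 0:
        raise ValueError("total_s must be positive")
    menu = list(state_menu)
    if not menu:
        raise ValueError("state_menu must not be empty")
    rng = np.random.default_rng(seed)
    hi = max(min_epoch_s, 2 * mean_epoch_s - min_epoch_s)
    records = []
    t = 0.0
    prev = None
    while t < total_s:
        dur = rng.uniform(min_epoch_s, hi)
        end = min(t + dur, total_s)
        choices = [m for m in menu if m != prev] or menu
        lab = choices[rng.integers(len(choices))]
        records.append((t, end, lab))
        prev = lab
        t = end
    return EpochSet.from_records(records)


def gen_spike_train(
    seed: int,
    schedule: EpochSet,
    params: SpikeGenParams | None = None,
    genotype: str = "WT",
    unit_id: str = "u0",
    p2v_width_us: float | None = None,
) -> tuple[SpikeTrain, SpikeTrainTruth]:
    """Generate one unit's spike train over a state schedule.

    Per epoch, tonic spikes follow the state's calibrated dead-time renewal
    process and burst events are planted as clusters of 2-5 spikes at 3-5 ms
    intra-burst intervals, each preceded by an enforced silent window. KO
    genotype forces the burst event rate to zero in every state. Returns the
    train together with its latent truth (burst onsets and sizes).
    """
    params = params or default_wt_params()
    if genotype not in ("WT", "KO"):
        raise ValueError(f"unknown genotype {genotype!r}")
    rng = np.random.default_rng(seed)
    pre_s = params.pre_burst_silence_ms / 1000.0
    gap_s = params.tonic_min_isi_ms / 1000.0
    burst_dead = pre_s + params.max_burst_span_s

    tonic_all: list[np.ndarray] = []
    onsets_all: list[np.ndarray] = []
    burst_spikes: list[np.ndarray] = []
    burst_counts: list[int] = []

    for s0, s1, lab in zip(schedule.starts_s, schedule.ends_s, schedule.labels):
        try:
            sp = params.states[lab]
        except KeyError:
            raise KeyError(f"no generator parameters for state {lab!r}") from None
        burst_rate = 0.0 if genotype == "KO" else sp.burst_event_rate_per_min / 60.0
        onsets = _dead_time_renewal(
            rng, burst_rate, burst_dead, s0, s1 - params.max_burst_span_s,
            what="burst event",
        )
        for onset in onsets:
            n = int(rng.integers(params.spikes_per_burst[0], params.spikes_per_burst[1] + 1))
            isis = rng.uniform(*params.intra_burst_isi_ms, size=n - 1) / 1000.0
            burst_spikes.append(onset + np.concatenate([[0.0], np.cumsum(isis)]))
            burst_counts.append(n)
        onsets_all.append(onsets)
        tonic_all.append(
            _dead_time_renewal(rng, sp.tonic_rate_hz, gap_s, s0, s1, what="tonic")
        )

    onsets = np.concatenate(onsets_all) if onsets_all else np.empty(0)
    tonic = np.concatenate(tonic_all) if tonic_all else np.empty(0)
    order = np.argsort(onsets)
    onsets = onsets[order]
    burst_spikes = [burst_spikes[i] for i in order]
    burst_counts = [burst_counts[i] for i in order]
    tonic.sort()

    # carve out each burst's silent surround from the tonic stream
    if onsets.size and tonic.size:
        keep = np.ones(tonic.size, dtype=bool)
        for onset, bsp in zip(onsets, burst_spikes):
            lo = np.searchsorted(tonic, onset - pre_s, side="left")
            hi = np.searchsorted(tonic, bsp[-1] + gap_s, side="right")
            keep[lo:hi] = False
        tonic = tonic[keep]

    # epoch joins can put two tonic spikes closer than the dead time; drop the
    # later one so no tonic ISI ever enters the burst-like range
    if tonic.size > 1:
        keep = np.ones(tonic.size, dtype=bool)
        last = tonic[0]
        for i in range(1, tonic.size):
            if tonic[i] - last < gap_s:
                keep[i] = False
            else:
                last = tonic[i]
        tonic = tonic[keep]

    all_spikes = np.sort(
        np.concatenate([tonic] + burst_spikes) if burst_spikes else tonic
    )
    train = SpikeTrain(unit_id, all_spikes, p2v_width_us)
    truth = SpikeTrainTruth(
        burst_onsets_s=onsets,
        burst_spike_counts=np.asarray(burst_counts, dtype=int),
        genotype=genotype,
        n_tonic_spikes=int(tonic.size),
    )
    return train, truth


# ---------------------------------------------------------------------------
# motion traces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotionEpisode:
    """A planted low-motion episode (level is a fraction of baseline mean)."""

    onset_s: float
    duration_s: float
    level_frac: float = 0.02  # quiescence: sensor-noise floor, ~2% of baseline

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class MotionGenParams:
    """Forced-walking-trace settings.

    The trace holds a stable walking baseline for ``baseline_duration_s``
    (the pre-injection treadmill period), then continues at walking level
    except inside planted episodes. Fluctuations are positive, autocorrelated
    (white noise smoothed over ``smoothing_s``) and proportional to the local
    level, so quiescent episodes have near-zero mean and variability.
    """

    total_s: float = 2400.0
    baseline_duration_s: float = 600.0
    baseline_mean: float = 1.0
    noise_cv: float = 0.3
    smoothing_s: float = 0.5
    episodes: Sequence[MotionEpisode] = ()

    def __post_init__(self) -> None:
        eps = sorted(self.episodes, key=lambda e: e.onset_s)
        for e in eps:
            if e.level_frac < 0:
                raise ValueError("episode level must be non-negative")
            if e.onset_s < self.baseline_duration_s:
                raise ValueError("episodes must start after the baseline period")
            if e.end_s > self.total_s:
                raise ValueError(
                    f"episode ending at {e.end_s:g} s exceeds trace end "
                    f"{self.total_s:g} s"
                )
        for a, b in zip(eps[:-1], eps[1:]):
            if a.end_s > b.onset_s:
                raise ValueError("episodes must not overlap")
        self.episodes = tuple(eps)


@dataclass
class MotionTruth:
    """Planted-episode ground truth of a generated motion trace."""

    episodes: tuple[MotionEpisode, ...]
    scalar_activity: np.ndarray  # the latent non-negative activity envelope


def gen_motion_trace(
    seed: int,
    params: MotionGenParams,
    mode: str = "accelerometer",
    sample_rate_hz: float = 100.0,
) -> tuple[MotionSignal, MotionTruth]:
    """Generate a motion trace with planted quiescent/low-motion episodes.

    In accelerometer mode the scalar activity envelope is spread over three
    axes by a slowly rotating unit vector scaled by ``sqrt(3)``, plus a 1 g
    gravity offset on z, so that the per-sample RMS over channels reproduces
    the scalar ground truth exactly (before band-pass filtering). Video mode
    returns the scalar itself as a single channel.
    """
    if mode not in ("accelerometer", "video"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    n = int(round(params.total_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz

    level = np.full(n, params.baseline_mean)
    for ep in params.episodes:
        i0 = int(round(ep.onset_s * sample_rate_hz))
        i1 = int(round(ep.end_s * sample_rate_hz))
        level[i0:i1] = ep.level_frac * params.baseline_mean

    # positive autocorrelated fluctuation: boxcar-smoothed white noise
    k = max(1, int(round(params.smoothing_s * sample_rate_hz)))
    white = rng.standard_normal(n + k - 1)
    smooth = np.convolve(white, np.ones(k) / k, mode="valid")
    smooth = smooth / max(np.std(smooth), 1e-12)
    activity = level * np.clip(1.0 + params.noise_cv * smooth, 0.05, None)

    if mode == "video":
        signal = MotionSignal(sample_rate_hz, activity[None, :])
    else:
        # slowly rotating unit direction in the analysis passband (~3 Hz)
        f_carrier = 3.0
        phase = 2 * np.pi * f_carrier * t + rng.uniform(0, 2 * np.pi)
        tilt = 2 * np.pi * 0.2 * t
        u = np.vstack(
            [
                np.sin(phase) * np.cos(tilt),
                np.sin(phase) * np.sin(tilt),
                np.cos(phase),
            ]
        )
        channels = np.sqrt(3.0) * activity * u
        channels[2] += 1.0  # gravity DC offset, removed by the band-pass
        signal = MotionSignal(sample_rate_hz, channels)
    return signal, MotionTruth(tuple(params.episodes), activity)


def gen_waveform_widths(
    seed: int,
    n_wide: int,
    n_narrow: int,
    wide_range_us: tuple[float, float] = (300.0, 500.0),
    narrow_range_us: tuple[float, float] = (150.0, 220.0),
) -> np.ndarray:
    """Peak-to-valley width fixture for the 250 us regular/narrow-spiking split.

    Returns exactly ``n_wide`` widths in the wide range and ``n_narrow`` in
    the narrow range, shuffled; both ranges must lie strictly on their side
    of 250 us.
    """
    if not (wide_range_us[0] > 250 and wide_range_us[0] <= wide_range_us[1]):
        raise ValueError("wide range must lie strictly above 250 us")
    if not (narrow_range_us[1] < 250 and narrow_range_us[0] <= narrow_range_us[1]):
        raise ValueError("narrow range must lie strictly below 250 us")
    rng = np.random.default_rng(seed)
    widths = np.concatenate(
        [
            rng.uniform(*wide_range_us, size=n_wide),
            rng.uniform(*narrow_range_us, size=n_narrow),
        ]
    )
    rng.shuffle(widths)
    return widths
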