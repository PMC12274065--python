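"""On-disk table formats and session validation.

All times are seconds, 0-based from recording start. Epochs are half-open
``[start, end)`` intervals, so a spike exactly at an epoch end belongs to the
next interval and no event is double counted.

Dialects are fixed so that tests are bit-exact: spikes / epochs / pulses are
tab-separated with a mandatory header row; motion signals are comma-separated.
Floats are written with six significant digits and round-trip at that
precision.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, InitVar
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Brain/behavior state labels accepted in epoch tables. Unknown labels are
#: rejected on read rather than dropped: silent loss would corrupt every
#: per-state statistic downstream.
VALID_STATE_LABELS = frozenset(
    {"walk", "wake", "NREM", "REM", "fLOM", "LOM", "nonwalk"}
)

#: Minimum sampling rate accepted for 3-axis accelerometer signals (the
#: band-pass analysis needs headroom above its 20 Hz upper cutoff).
MIN_ACCEL_RATE_HZ = 50.0


class FormatError(ValueError):
    """A file does not conform to the documented TSV/CSV dialect."""


class SessionValidationError(ValueError):
    """A structural invariant of a session component is violated."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise SessionValidationError(msg)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SpikeTrain:
    """Sorted spike times of one single unit.

    Parameters
    ----------
    unit_id
        Identifier carried through every results table.
    spike_times_s
        Strictly increasing, non-negative spike times in seconds.
    p2v_width_us
        Optional peak-to-valley spike-waveform width in microseconds, used
        for regular-spiking vs narrow-spiking classification.
    """

    unit_id: str
    spike_times_s: np.ndarray
    p2v_width_us: float | None = None
    validate: InitVar[bool] = True

    def __post_init__(self, validate: bool) -> None:
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)
        if validate:
            for msg in self.diagnostics():
                raise SessionValidationError(msg)

    def diagnostics(self) -> list[str]:
        out: list[str] = []
        t = self.spike_times_s
        if t.ndim != 1:
            return [f"unit {self.unit_id}: spike times must be 1-D"]
        if t.size and t[0] < 0:
            out.append(f"unit {self.unit_id}: negative spike time {t[0]}")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            out.append(f"unit {self.unit_id}: spike times not strictly increasing")
        if self.p2v_width_us is not None and not self.p2v_width_us > 0:
            out.append(f"unit {self.unit_id}: non-positive waveform width")
        return out

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times_s.size)

    def count_in(self, start_s: float, end_s: float) -> int:
        """Number of spikes in the half-open interval [start_s, end_s)."""
        lo, hi = np.searchsorted(self.spike_times_s, [start_s, end_s], side="left")
        return int(hi - lo)


@dataclass
class EpochSet:
    """Labeled half-open time intervals defining brain/behavior states."""

    starts_s: np.ndarray
    ends_s: np.ndarray
    labels: np.ndarray
    validate: InitVar[bool] = True

    def __post_init__(self, validate: bool) -> None:
        self.starts_s = np.asarray(self.starts_s, dtype=float)
        self.ends_s = np.asarray(self.ends_s, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if validate:
            for msg in self.diagnostics():
                raise SessionValidationError(msg)

    @classmethod
    def from_records(
        cls, epochs: Iterable[tuple[float, float, str]], validate: bool = True
    ) -> "EpochSet":
        rows = list(epochs)
        starts = np.array([r[0] for r in rows], dtype=float)
        ends = np.array([r[1] for r in rows], dtype=float)
        labels = np.array([r[2] for r in rows], dtype=object)
        return cls(starts, ends, labels, validate=validate)

    def diagnostics(self) -> list[str]:
        out: list[str] = []
        for i, (s, e, lab) in enumerate(zip(self.starts_s, self.ends_s, self.labels)):
            if lab not in VALID_STATE_LABELS:
                out.append(f"epoch row {i}: unknown label {lab!r}")
            if not s < e:
                out.append(f"epoch row {i}: end {e} <= start {s}")
        for lab in set(self.labels):
            idx = np.flatnonzero(self.labels == lab)
            order = idx[np.argsort(self.starts_s[idx])]
            for a, b in zip(order[:-1], order[1:]):
                if self.ends_s[a] > self.starts_s[b]:
                    out.append(
                        f"epoch rows {a} and {b}: overlapping {lab!r} intervals"
                    )
        return out

    def __len__(self) -> int:
        return int(self.starts_s.size)

    def intervals(self, label: str) -> np.ndarray:
        """(n, 2) array of [start, end) intervals carrying ``label``."""
        mask = self.labels == label
        return np.column_stack([self.starts_s[mask], self.ends_s[mask]])

    def duration(self, label: str) -> float:
        iv = self.intervals(label)
        return float(np.sum(iv[:, 1] - iv[:, 0])) if iv.size else 0.0

    @property
    def present_labels(self) -> list[str]:
        seen: list[str] = []
        for lab in self.labels:
            if lab not in seen:
                seen.append(lab)
        return seen

    @property
    def span(self) -> tuple[float, float]:
        return float(self.starts_s.min()), float(self.ends_s.max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"start_s": self.starts_s, "end_s": self.ends_s, "label": self.labels}
        )


@dataclass
class MotionSignal:
    """Uniformly sampled motion recording.

    ``channels`` has shape (n_channels, n_samples): three rows of acceleration
    in g for accelerometer mode, one row of arbitrary-unit per-frame motion
    for video mode.
    """

    sample_rate_hz: float
    channels: np.ndarray
    t0_s: float = 0.0
    validate: InitVar[bool] = True

    def __post_init__(self, validate: bool) -> None:
        self.channels = np.atleast_2d(np.asarray(self.channels, dtype=float))
        if validate:
            for msg in self.diagnostics():
                raise SessionValidationError(msg)

    def diagnostics(self) -> list[str]:
        out: list[str] = []
        if not self.sample_rate_hz > 0:
            out.append("motion: sample_rate_hz must be positive")
        if self.channels.shape[0] not in (1, 3):
            out.append(
                f"motion: expected 1 (video) or 3 (accelerometer) channels, "
                f"got {self.channels.shape[0]}"
            )
        if self.channels.shape[0] == 3 and self.sample_rate_hz < MIN_ACCEL_RATE_HZ:
            out.append(
                f"motion: accelerometer mode needs >= {MIN_ACCEL_RATE_HZ:g} Hz, "
                f"got {self.sample_rate_hz:g}"
            )
        return out

    @property
    def mode(self) -> str:
        return "accelerometer" if self.channels.shape[0] == 3 else "video"

    @property
    def n_samples(self) -> int:
        return int(self.channels.shape[1])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_samples) / self.sample_rate_hz


@dataclass
class PulseProtocol:
    """Stimulation pulse onsets and per-pulse durations."""

    onsets_s: np.ndarray
    widths_s: np.ndarray
    meta: dict = field(default_factory=dict)
    validate: InitVar[bool] = True

    def __post_init__(self, validate: bool) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        self.widths_s = np.broadcast_to(
            np.asarray(self.widths_s, dtype=float), self.onsets_s.shape
        ).copy()
        if validate:
            for msg in self.diagnostics():
                raise SessionValidationError(msg)

    def diagnostics(self) -> list[str]:
        out: list[str] = []
        if self.onsets_s.size and not np.all(self.widths_s > 0):
            out.append("pulses: widths must be positive")
        if self.onsets_s.size > 1:
            if not np.all(np.diff(self.onsets_s) > 0):
                out.append("pulses: onsets not strictly increasing")
            elif np.any(
                self.onsets_s[:-1] + self.widths_s[:-1] > self.onsets_s[1:]
            ):
                out.append("pulses: overlapping pulses")
        return out

    @property
    def n_pulses(self) -> int:
        return int(self.onsets_s.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"onset_s": self.onsets_s, "width_s": self.widths_s})


@dataclass
class Session:
    """A validated bundle of the inputs one recording contributes."""

    spike_trains: list[SpikeTrain] = field(default_factory=list)
    epochs: EpochSet | None = None
    motion: MotionSignal | None = None
    pulses: PulseProtocol | None = None
    injection_time_s: float | None = None
    config: dict = field(default_factory=dict)

    @property
    def span(self) -> tuple[float, float] | None:
        """Recording span inferred from whatever components are present."""
        hi = 0.0
        lo = np.inf
        seen = False
        for tr in self.spike_trains:
            if tr.n_spikes:
                lo = min(lo, tr.spike_times_s[0])
                hi = max(hi, tr.spike_times_s[-1])
                seen = True
        if self.epochs is not None and len(self.epochs):
            s, e = self.epochs.span
            lo, hi, seen = min(lo, s), max(hi, e), True
        if self.motion is not None:
            lo = min(lo, self.motion.t0_s)
            hi = max(hi, self.motion.t0_s + self.motion.duration_s)
            seen = True
        return (float(lo), float(hi)) if seen else None


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_table(path: str | Path, sep: str, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: unreadable table ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}, line 1: missing required column(s) {missing}; "
            f"found {list(df.columns)}"
        )
    return df


def read_spikes(path: str | Path) -> list[SpikeTrain]:
    """Read ``spikes.tsv`` (columns unit_id, time_s[, p2v_width_us])."""
    df = _read_table(path, "\t", ["unit_id", "time_s"])
    trains = []
    for unit, grp in df.groupby("unit_id", sort=True):
        width = None
        if "p2v_width_us" in grp.columns:
            w = grp["p2v_width_us"].dropna()
            if len(w):
                width = float(w.iloc[0])
        times = grp["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0) or (times.size and times[0] < 0):
            raise SessionValidationError(
                f"{path}: unit {unit!r} has non-monotone or negative times"
            )
        trains.append(SpikeTrain(str(unit), times, width))
    return trains


def read_epochs(path: str | Path) -> EpochSet:
    """Read ``epochs.tsv`` (columns start_s, end_s, label)."""
    df = _read_table(path, "\t", ["start_s", "end_s", "label"])
    es = EpochSet(
        df["start_s"].to_numpy(float),
        df["end_s"].to_numpy(float),
        df["label"].to_numpy(object),
        validate=False,
    )
    diags = es.diagnostics()
    if diags:
        raise SessionValidationError(f"{path}: " + "; ".join(diags))
    return es


def read_motion(path: str | Path) -> MotionSignal:
    """Read ``motion.csv``: time_s + (ax_g, ay_g, az_g) or a single motion column."""
    df = _read_table(path, ",", ["time_s"])
    t = df["time_s"].to_numpy(float)
    if t.size < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise SessionValidationError(f"{path}: non-uniform sampling")
    if {"ax_g", "ay_g", "az_g"}.issubset(df.columns):
        channels = df[["ax_g", "ay_g", "az_g"]].to_numpy(float).T
    elif "motion" in df.columns:
        channels = df[["motion"]].to_numpy(float).T
    else:
        raise FormatError(
            f"{path}, line 1: expected ax_g/ay_g/az_g or motion columns"
        )
    return MotionSignal(1.0 / dt[0], channels, t0_s=float(t[0]))


def read_pulses(path: str | Path) -> PulseProtocol:
    """Read ``pulses.tsv`` (columns onset_s, width_s)."""
    df = _read_table(path, "\t", ["onset_s", "width_s"])
    return PulseProtocol(
        df["onset_s"].to_numpy(float), df["width_s"].to_numpy(float)
    )


def read_session(
    paths: Mapping[str, str | Path], config: Mapping | None = None
) -> Session:
    """Assemble and validate a session from a map of file paths.

    Recognized keys: ``spikes``, ``epochs``, ``motion``, ``pulses``. The
    config mapping may carry ``injection_time_s``.
    """
    config = dict(config or {})
    session = Session(config=config)
    if "spikes" in paths:
        session.spike_trains = read_spikes(paths["spikes"])
    if "epochs" in paths:
        session.epochs = read_epochs(paths["epochs"])
    if "motion" in paths:
        session.motion = read_motion(paths["motion"])
    if "pulses" in paths:
        session.pulses = read_pulses(paths["pulses"])
    if "injection_time_s" in config:
        session.injection_time_s = float(config["injection_time_s"])
    diags = validate_session(session)
    if diags:
        raise SessionValidationError("; ".join(diags))
    return session


def validate_session(session: Session) -> list[str]:
    """Collect structural diagnostics; empty list iff the session is valid."""
    out: list[str] = []
    for tr in session.spike_trains:
        out.extend(tr.diagnostics())
    if session.epochs is not None:
        out.extend(session.epochs.diagnostics())
    if session.motion is not None:
        out.extend(session.motion.diagnostics())
    if session.pulses is not None:
        out.extend(session.pulses.diagnostics())
    if session.injection_time_s is not None:
        span = session.span
        if span is not None and not (
            span[0] <= session.injection_time_s <= span[1]
        ):
            out.append(
                f"injection_time_s {session.injection_time_s} outside recording "
                f"span [{span[0]:g}, {span[1]:g}]"
            )
    return out


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.6g"


def write_results(table, path: str | Path) -> Path:
    """Write any results table as TSV with a header and 6-significant-digit floats.

    Accepts a DataFrame, a mapping (one row), or a dataclass with scalar
    fields. Column order is preserved (mappings keep insertion order), so
    repeated runs are byte-identical. Raises on an empty table rather than
    writing an empty file.
    """
    if hasattr(table, "to_frame_row"):
        df = table.to_frame_row()
    elif isinstance(table, pd.DataFrame):
        df = table
    elif isinstance(table, Mapping):
        df = pd.DataFrame([table])
    else:
        import dataclasses

        if dataclasses.is_dataclass(table):
            df = pd.DataFrame([dataclasses.asdict(table)])
        else:
            raise TypeError(f"cannot write results of type {type(table)!r}")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"refusing to write empty results table to {path}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def write_spikes(trains: Iterable[SpikeTrain], path: str | Path) -> Path:
    rows = []
    for tr in trains:
        for t in tr.spike_times_s:
            rows.append((tr.unit_id, t, tr.p2v_width_us))
    df = pd.DataFrame(rows, columns=["unit_id", "time_s", "p2v_width_us"])
    if df.shape[0] == 0:
        raise ValueError(f"refusing to write empty spikes table to {path}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # absolute times need sub-ms resolution even hours into a recording, so
    # the time column gets more digits than the generic 6-significant format
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def write_epochs(epochs: EpochSet, path: str | Path) -> Path:
    return write_results(epochs.to_frame(), path)


def write_pulses(pulses: PulseProtocol, path: str | Path) -> Path:
    return write_results(pulses.to_frame(), path)


def write_motion(signal: MotionSignal, path: str | Path) -> Path:
    cols = {"time_s": signal.times_s}
    if signal.mode == "accelerometer":
        for name, ch in zip(("ax_g", "ay_g", "az_g"), signal.channels):
            cols[name] = ch
    else:
        cols["motion"] = signal.channels[0]
    df = pd.DataFrame(cols)
    if df.shape[0] == 0:
        raise ValueError(f"refusing to write empty motion table to {path}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # the time column needs 10 ms resolution deep into a recording
    df.to_csv(path, sep=",", index=False, float_format="%.10g")
    return path
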