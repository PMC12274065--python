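"""Stimulation pulse-train constructors.

Three paradigms used to entrain thalamic firing modes:

- tonic-like: regular pulses at a fixed inter-pulse interval (20 Hz at the
  default 50 ms IPI),
- burst-like: short high-frequency pulse clusters (4 pulses at 4 ms
  intervals, i.e. 250 Hz within the cluster) repeated every second,
- phasic ON-OFF: long inhibitory pulses alternating with equal silent
  periods (1 s ON - 1 s OFF, 50% duty cycle).

Protocols start at t = 0 of their own clock; callers shift onsets into
session time. Pulse widths are always explicit because different hardware in
the same paradigm used different widths (6.25 ms optogenetic vs 0.1 ms
electric pulses).
"""

from __future__ import annotations

import numpy as np

from .io_formats import PulseProtocol

__all__ = ["tonic_protocol", "burst_protocol", "phasic_onoff_protocol"]


def tonic_protocol(
    ipi_ms: float = 50.0, width_ms: float = 6.25, duration_s: float = 60.0
) -> PulseProtocol:
    """Regular pulse train: onsets at 0, ipi, 2*ipi, ... strictly below duration."""
    if width_ms >= ipi_ms:
        raise ValueError(
            f"pulse width {width_ms:g} ms would overlap the next pulse at "
            f"{ipi_ms:g} ms IPI"
        )
    ipi_s = ipi_ms / 1000.0
    n = int(np.ceil(duration_s / ipi_s - 1e-12))
    onsets = np.arange(n) * ipi_s
    onsets = onsets[onsets < duration_s]
    return PulseProtocol(
        onsets,
        np.full(onsets.size, width_ms / 1000.0),
        meta={
            "kind": "tonic",
            "ipi_ms": ipi_ms,
            "rate_hz": 1000.0 / ipi_ms,
            "pulse_width_ms": width_ms,
            "duration_s": duration_s,
        },
    )


def burst_protocol(
    n_pulses: int = 4,
    intra_ipi_ms: float = 4.0,
    inter_burst_s: float = 1.0,
    width_ms: float = 0.1,
    duration_s: float = 10.0,
) -> PulseProtocol:
    """Burst-like train: clusters of pulses repeated at the inter-burst interval.

    Within each cluster, pulses sit at multiples of ``intra_ipi_ms`` (the
    default 4 ms gives a 250 Hz instantaneous rate); clusters start at 0,
    ``inter_burst_s``, ... and a whole cluster must fit inside one inter-burst
    interval.
    """
    if n_pulses < 2:
        raise ValueError("a burst needs at least 2 pulses")
    if width_ms >= intra_ipi_ms:
        raise ValueError("pulse width must be below the intra-burst interval")
    span_s = ((n_pulses - 1) * intra_ipi_ms + width_ms) / 1000.0
    if span_s >= inter_burst_s:
        raise ValueError(
            f"burst span {span_s:g} s does not fit the {inter_burst_s:g} s "
            "inter-burst interval"
        )
    burst_starts = np.arange(0.0, duration_s, inter_burst_s)
    offsets = np.arange(n_pulses) * intra_ipi_ms / 1000.0
    onsets = (burst_starts[:, None] + offsets[None, :]).ravel()
    onsets = onsets[onsets < duration_s]
    return PulseProtocol(
        onsets,
        np.full(onsets.size, width_ms / 1000.0),
        meta={
            "kind": "burst",
            "n_pulses": n_pulses,
            "intra_ipi_ms": intra_ipi_ms,
            "intra_burst_rate_hz": 1000.0 / intra_ipi_ms,
            "inter_burst_s": inter_burst_s,
            "pulse_width_ms": width_ms,
            "duration_s": duration_s,
        },
    )


def phasic_onoff_protocol(
    on_s: float = 1.0, off_s: float = 1.0, duration_s: float = 3600.0
) -> PulseProtocol:
    """Alternating ON-OFF pulses (ON pulses of ``on_s`` separated by ``off_s``).

    The final pulse is truncated at the protocol end, preserving the duty
    cycle ``on / (on + off)`` over whole cycles.
    """
    if on_s <= 0 or off_s <= 0:
        raise ValueError("ON and OFF durations must be positive")
    cycle = on_s + off_s
    onsets = np.arange(0.0, duration_s, cycle)
    widths = np.minimum(on_s, duration_s - onsets)
    keep = widths > 0
    return PulseProtocol(
        onsets[keep],
        widths[keep],
        meta={
            "kind": "phasic_onoff",
            "on_s": on_s,
            "off_s": off_s,
            "duty_cycle": on_s / cycle,
            "duration_s": duration_s,
        },
    )
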