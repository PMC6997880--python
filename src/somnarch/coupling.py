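"""SO-fast-spindle coupling: nesting, delay to the down-state, dispersion.

A slow oscillation "hosts" a spindle when the spindle's anchor (its
maximum-envelope time) falls between the SO's lowest trough (down-state)
and 0.5 s after the terminal positive-to-negative zero crossing that ends
the up-state.  Each spindle is counted once, for the earliest SO whose
window contains it on the same channel.  The delay is anchor minus trough
time; its mean and standard deviation ("delay dispersion") summarise the
temporal precision of the co-occurrence.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import EventList, Recording, SleepEvent

__all__ = ["CouplingSummary", "couple_so_spindles", "event_locked_average"]

#: seconds past the SO's terminal positive-to-negative zero crossing within
#: which a spindle still counts as nested
WINDOW_EXTENSION_S = 0.5


@dataclass
class CouplingSummary:
    """Per-channel coupling statistics plus the per-pair assignment table."""

    per_channel: pd.DataFrame  # indexed by channel
    pairs: pd.DataFrame  # so_id, spindle_id, channel, delay_s

    @property
    def n_coupled(self) -> int:
        return len(self.pairs)

    def channel(self, label: str) -> pd.Series:
        return self.per_channel.loc[label]


def _anchor(e: SleepEvent) -> float:
    """Spindle reference point: envelope peak, falling back to the trough."""
    return e.peak_time if np.isfinite(e.peak_time) else e.trough_time


def couple_so_spindles(
    so: EventList,
    spindles: EventList,
    window_extension_s: float = WINDOW_EXTENSION_S,
) -> CouplingSummary:
    """Assign fast spindles to slow oscillations and summarise the delays.

    For each SO the nesting window is ``[trough_time, offset +
    window_extension_s]`` (offset being the terminal positive-to-negative
    zero crossing).  Spindles are assigned to the earliest SO whose window
    contains their anchor, at most once per channel.
    """
    so_channels = {e.channel for e in so}
    sp_channels = {e.channel for e in spindles}
    if so_channels and sp_channels and not (so_channels & sp_channels):
        raise ValueError(
            f"event lists share no channel: SO on {sorted(so_channels)}, "
            f"spindles on {sorted(sp_channels)}"
        )

    pair_rows = []
    chan_rows = {}
    for ch in sorted(so_channels | sp_channels):
        sos = sorted(
            (e for e in so if e.channel == ch), key=lambda e: e.trough_time
        )
        sps = sorted((e for e in spindles if e.channel == ch), key=_anchor)
        taken: set[int] = set()
        coupled_so, coupled_sp, delays = [], [], []
        for si, s in enumerate(sos):
            lo, hi = s.trough_time, s.offset + window_extension_s
            for pi, p in enumerate(sps):
                if pi in taken:
                    continue
                t = _anchor(p)
                if lo <= t <= hi:
                    taken.add(pi)
                    delays.append(t - s.trough_time)
                    coupled_so.append(s)
                    coupled_sp.append(p)
                    pair_rows.append(
                        {
                            "channel": ch,
                            "so_id": si,
                            "spindle_id": pi,
                            "so_trough_s": s.trough_time,
                            "spindle_anchor_s": t,
                            "delay_s": t - s.trough_time,
                        }
                    )
        delays = np.asarray(delays)
        chan_rows[ch] = {
            "n_coupled": len(delays),
            "mean_delay_s": delays.mean() if delays.size else np.nan,
            "delay_sd_s": delays.std(ddof=1) if delays.size >= 2 else np.nan,
            "coupled_so_amp_uv": (
                np.mean([e.amplitude for e in coupled_so]) if coupled_so else np.nan
            ),
            "coupled_so_dur_s": (
                np.mean([e.duration for e in coupled_so]) if coupled_so else np.nan
            ),
            "coupled_spindle_amp_uv": (
                np.mean([e.amplitude for e in coupled_sp]) if coupled_sp else np.nan
            ),
            "coupled_spindle_dur_s": (
                np.mean([e.duration for e in coupled_sp]) if coupled_sp else np.nan
            ),
        }
    per_channel = pd.DataFrame.from_dict(chan_rows, orient="index")
    per_channel.index.name = "channel"
    pairs = pd.DataFrame(
        pair_rows,
        columns=[
            "channel",
            "so_id",
            "spindle_id",
            "so_trough_s",
            "spindle_anchor_s",
            "delay_s",
        ],
    )
    return CouplingSummary(per_channel=per_channel, pairs=pairs)


def event_locked_average(
    rec: Recording,
    events: EventList,
    window_s: float = 1.2,
    channel: str | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Average signal segments time-locked to event troughs (trough at t=0).

    Returns ``(times, mean_waveform, n_dropped)``; events closer than
    ``window_s`` to a recording edge are dropped and counted.
    """
    if len(events) == 0:
        raise ValueError("cannot average an empty event list")
    half = int(round(window_s * rec.rate))
    segs = []
    dropped = 0
    for e in events:
        if channel is not None and e.channel != channel:
            continue
        t = e.trough_time if np.isfinite(e.trough_time) else 0.5 * (e.onset + e.offset)
        i = int(round(t * rec.rate))
        if i - half < 0 or i + half + 1 > rec.n_samples:
            dropped += 1
            continue
        segs.append(rec.get(e.channel)[i - half : i + half + 1])
    if not segs:
        raise ValueError("no event has a full window inside the recording")
    times = np.arange(-half, half + 1) / rec.rate
    return times, np.mean(segs, axis=0), dropped
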