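"""Domain types and file I/O shared by every analysis stage.

Conventions used throughout the package:

* time is measured in seconds from the start of the recording, 0-based;
* all intervals are half-open ``[start, end)``;
* 30-s scoring epochs are 0-indexed;
* signal amplitudes are in microvolts (µV).
"""
from __future__ import annotations

import io
import struct
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "Channel",
    "Recording",
    "Hypnogram",
    "ArtifactMask",
    "SleepEvent",
    "EventList",
    "read_recording",
    "write_recording",
    "read_hypnogram",
    "write_hypnogram",
    "read_events",
    "write_events",
    "read_arousals",
    "merge_intervals",
]

#: Canonical stage vocabulary.  ``SWS`` is the native token for slow-wave
#: sleep; ``N3`` is accepted on input as an alias.
STAGES = ("W", "N1", "N2", "SWS", "REM", "UNSCORED")
STAGE_ALIASES = {"N3": "SWS"}
SLEEP_STAGES = frozenset({"N1", "N2", "SWS", "REM"})
NREM_STAGES = frozenset({"N1", "N2", "SWS"})

CHANNEL_KINDS = ("EEG", "EOG", "EMG", "ECG")

#: Default EDF physical ranges (µV) per channel kind; they bound the 16-bit
#: quantization error well below any detection threshold used downstream.
DEFAULT_PHYSICAL_RANGE = {"EEG": 1000.0, "EOG": 1000.0, "EMG": 500.0, "ECG": 1000.0}


class FormatError(ValueError):
    """Raised when an input file cannot be interpreted."""


def infer_channel_kind(label: str) -> str:
    """Guess the signal kind from a channel label (10-20 names default to EEG)."""
    up = label.upper()
    for kind in ("EMG", "EOG", "ECG"):
        if kind in up or (kind == "ECG" and "EKG" in up):
            return kind
    return "EEG"


@dataclass(frozen=True)
class Channel:
    label: str
    kind: str = "EEG"

    def __post_init__(self):
        if self.kind not in CHANNEL_KINDS:
            raise ValueError(f"unknown channel kind {self.kind!r}")


@dataclass
class Recording:
    """Uniformly sampled multichannel PSG signal in µV.

    ``data`` has shape ``(n_channels, n_samples)``; ``reference`` records
    whether the montage is ``"raw"`` or ``"linked-mastoid"``.
    """

    data: np.ndarray
    rate: float
    channels: list[Channel]
    start_time: datetime | None = None
    reference: str = "raw"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channels):
            raise ValueError("channel list does not match data rows")
        if self.data.shape[1] == 0:
            raise FormatError("recording holds zero samples")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if np.isnan(self.data).any():
            raise ValueError("recording contains NaNs")

    # -- convenience -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.channels]

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def get(self, label: str) -> np.ndarray:
        return self.data[self.channel_index(label)]

    def labels_of_kind(self, kind: str) -> list[str]:
        return [c.label for c in self.channels if c.kind == kind]

    def pick(self, labels: list[str]) -> "Recording":
        idx = [self.channel_index(l) for l in labels]
        return replace(
            self,
            data=self.data[idx].copy(),
            channels=[self.channels[i] for i in idx],
        )


@dataclass
class Hypnogram:
    """Per-epoch stage sequence with the lights-off/lights-on window."""

    stages: list[str]
    epoch_s: float = 30.0
    lights_off: float = 0.0
    lights_on: float | None = None

    def __post_init__(self):
        if self.epoch_s <= 0:
            raise ValueError("epoch length must be positive")
        self.stages = [STAGE_ALIASES.get(s, s) for s in self.stages]
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stage token(s): {sorted(set(bad))}")
        if self.lights_on is None:
            self.lights_on = len(self.stages) * self.epoch_s
        if not self.lights_off < self.lights_on:
            raise ValueError("lights_off must precede lights_on")
        if len(self.stages) * self.epoch_s < self.lights_on - self.lights_off:
            raise ValueError("hypnogram shorter than the lights window")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def duration(self) -> float:
        return self.n_epochs * self.epoch_s

    def epoch_bounds(self, i: int) -> tuple[float, float]:
        return i * self.epoch_s, (i + 1) * self.epoch_s

    def epoch_of(self, t: float) -> int:
        return int(t // self.epoch_s)

    def stage_at(self, t: float) -> str:
        i = self.epoch_of(t)
        if not 0 <= i < self.n_epochs:
            raise ValueError(f"time {t} outside hypnogram")
        return self.stages[i]

    def epochs_of(self, stages) -> np.ndarray:
        """Indices of epochs whose stage lies in ``stages``."""
        want = set(stages)
        return np.array([i for i, s in enumerate(self.stages) if s in want], dtype=int)

    def sample_mask(self, stages, rate: float, n_samples: int) -> np.ndarray:
        """Boolean per-sample mask: True where the sample's epoch is in ``stages``."""
        mask = np.zeros(n_samples, dtype=bool)
        spe = self.epoch_s * rate
        for i in self.epochs_of(stages):
            a = int(round(i * spe))
            b = min(int(round((i + 1) * spe)), n_samples)
            mask[a:b] = True
        return mask

    def minutes_in(self, stages) -> float:
        return len(self.epochs_of(stages)) * self.epoch_s / 60.0


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Sort and merge overlapping/touching half-open intervals -> (k, 2) array."""
    arr = np.asarray(intervals, dtype=float).reshape(-1, 2)
    if arr.size == 0:
        return arr
    arr = arr[np.argsort(arr[:, 0])]
    out = [list(arr[0])]
    for a, b in arr[1:]:
        if a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return np.array(out)


@dataclass
class ArtifactMask:
    """Bad-signal intervals per channel plus their global union.

    Intervals are half-open ``[start, end)`` second ranges; they are
    normalised (sorted, merged) on construction.
    """

    per_channel: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.per_channel = {
            ch: merge_intervals(iv) for ch, iv in self.per_channel.items()
        }

    @property
    def global_intervals(self) -> np.ndarray:
        parts = [iv for iv in self.per_channel.values() if iv.size]
        if not parts:
            return np.empty((0, 2))
        return merge_intervals(np.vstack(parts))

    def masked_seconds(self) -> float:
        iv = self.global_intervals
        return float((iv[:, 1] - iv[:, 0]).sum()) if iv.size else 0.0

    def overlaps(self, start: float, end: float) -> bool:
        """True if [start, end) intersects the global union."""
        iv = self.global_intervals
        if not iv.size:
            return False
        return bool(((iv[:, 0] < end) & (iv[:, 1] > start)).any())

    def clean_sample_mask(self, rate: float, n_samples: int) -> np.ndarray:
        """Boolean per-sample mask: True where the sample is artifact-free."""
        mask = np.ones(n_samples, dtype=bool)
        for a, b in self.global_intervals:
            ia = max(int(np.floor(a * rate)), 0)
            ib = min(int(np.ceil(b * rate)), n_samples)
            mask[ia:ib] = False
        return mask

    def merged_with(self, other: "ArtifactMask") -> "ArtifactMask":
        per = {ch: iv.copy() for ch, iv in self.per_channel.items()}
        for ch, iv in other.per_channel.items():
            per[ch] = merge_intervals(np.vstack([per.get(ch, np.empty((0, 2))), iv]))
        return ArtifactMask(per)

    @classmethod
    def empty(cls) -> "ArtifactMask":
        return cls({})


EVENT_KINDS = ("slow_spindle", "fast_spindle", "so", "slow_wave")


@dataclass
class SleepEvent:
    """A single detected (or injected) NREM event.

    ``amplitude`` is peak-to-peak for spindles and slow waves and
    trough-to-peak for slow oscillations; ``trough_time`` marks the most
    negative sample, ``peak_time`` the event anchor used for coupling
    (maximum-envelope time for spindles, positive peak for SO).
    """

    kind: str
    channel: str
    onset: float
    offset: float
    trough_time: float = np.nan
    peak_time: float = np.nan
    amplitude: float = np.nan
    core_frequency: float = np.nan
    slope: float = np.nan

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not self.onset < self.offset:
            raise ValueError("onset must precede offset")
        if np.isfinite(self.trough_time) and not (
            self.onset <= self.trough_time <= self.offset
        ):
            raise ValueError("trough_time outside [onset, offset]")
        if np.isfinite(self.amplitude) and self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class EventList:
    """Ordered collection of events plus the density denominator.

    ``denominator_min`` holds the artifact-free minutes of the eligible
    stages used when quoting densities (events/min).
    """

    events: list[SleepEvent] = field(default_factory=list)
    provenance: str = ""
    denominator_min: float | None = None

    def __post_init__(self):
        self.events = sorted(self.events, key=lambda e: (e.channel, e.onset))

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def filter(self, kind: str | None = None, channel: str | None = None) -> "EventList":
        ev = [
            e
            for e in self.events
            if (kind is None or e.kind == kind)
            and (channel is None or e.channel == channel)
        ]
        return EventList(ev, self.provenance, self.denominator_min)

    def density_per_min(self, channel: str | None = None) -> float:
        if not self.denominator_min:
            raise ValueError("denominator_min is not set")
        return len(self.filter(channel=channel)) / self.denominator_min

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "kind": e.kind,
                "channel": e.channel,
                "onset_s": e.onset,
                "offset_s": e.offset,
                "trough_s": e.trough_time,
                "amplitude_uv": e.amplitude,
                "duration_s": e.duration,
                "core_freq_hz": e.core_frequency,
                "slope_uv_per_s": e.slope,
            }
            for e in self.events
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "kind",
                "channel",
                "onset_s",
                "offset_s",
                "trough_s",
                "amplitude_uv",
                "duration_s",
                "core_freq_hz",
                "slope_uv_per_s",
            ],
        )


# ---------------------------------------------------------------------------
# EDF signals
# ---------------------------------------------------------------------------

def read_recording(path, channel_kinds: dict[str, str] | None = None) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` (µV).

    Channel kinds are inferred from labels; ``channel_kinds`` overrides the
    inference per label.  Signals with differing rates are resampled on read
    to the maximum common rate by MNE.
    """
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises a zoo of types for malformed files
        raise FormatError(f"cannot read EDF file {path}: {exc}") from exc
    if raw.n_times == 0:
        raise FormatError(f"EDF file {path} holds zero samples")
    data = raw.get_data() * 1e6  # MNE returns volts for EEG-like channels
    channels = []
    for label in raw.ch_names:
        kind = (channel_kinds or {}).get(label, infer_channel_kind(label))
        channels.append(Channel(label, kind))
    start = None
    if raw.info.get("meas_date") is not None:
        start = raw.info["meas_date"].replace(tzinfo=None)
    return Recording(
        data=data,
        rate=float(raw.info["sfreq"]),
        channels=channels,
        start_time=start,
    )


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_recording(
    rec: Recording, path, physical_range: dict[str, float] | None = None
) -> None:
    """Write a :class:`Recording` to EDF (16-bit, 1-s data records).

    No installed library writes EDF, so the format is emitted directly; the
    layout is the plain EDF specification (256-byte global header, per-signal
    header fields, little-endian int16 data records).  Physical ranges are
    per channel kind (µV), default ±1000 for EEG/EOG/ECG and ±500 for EMG;
    samples outside the range are a validation error rather than a silent
    clip.  The recording must span a whole number of seconds.
    """
    if np.isnan(rec.data).any():  # Recording forbids NaN, but guard anyway
        raise ValueError("recording contains NaNs")
    rate = rec.rate
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(rate))  # samples per 1-s record
    if rec.n_samples % spr:
        raise ValueError(
            "EDF writer requires a whole number of seconds; "
            f"got {rec.n_samples} samples at {spr} Hz"
        )
    n_records = rec.n_samples // spr
    ranges = dict(DEFAULT_PHYSICAL_RANGE)
    if physical_range:
        ranges.update(physical_range)

    start = rec.start_time or datetime(2000, 1, 1, 0, 0, 0)
    n_sig = len(rec.channels)
    header_bytes = 256 * (1 + n_sig)

    buf = io.BytesIO()
    buf.write(_edf_field("0", 8))
    buf.write(_edf_field("X X X X", 80))
    buf.write(_edf_field("Startdate X X X X", 80))
    buf.write(_edf_field(start.strftime("%d.%m.%y"), 8))
    buf.write(_edf_field(start.strftime("%H.%M.%S"), 8))
    buf.write(_edf_field(header_bytes, 8))
    buf.write(_edf_field("", 44))
    buf.write(_edf_field(n_records, 8))
    buf.write(_edf_field("1", 8))
    buf.write(_edf_field(n_sig, 4))

    phys = []
    for ch in rec.channels:
        r = ranges.get(ch.kind, 1000.0)
        phys.append(r)
    for ch in rec.channels:
        buf.write(_edf_field(ch.label, 16))
    for _ in rec.channels:
        buf.write(_edf_field("", 80))
    for _ in rec.channels:
        buf.write(_edf_field("uV", 8))
    for r in phys:
        buf.write(_edf_field(f"{-r:g}", 8))
    for r in phys:
        buf.write(_edf_field(f"{r:g}", 8))
    for _ in rec.channels:
        buf.write(_edf_field(-32768, 8))
    for _ in rec.channels:
        buf.write(_edf_field(32767, 8))
    for _ in rec.channels:
        buf.write(_edf_field("", 80))
    for _ in rec.channels:
        buf.write(_edf_field(spr, 8))
    for _ in rec.channels:
        buf.write(_edf_field("", 32))

    digital = np.empty_like(rec.data, dtype=np.int16)
    for i, (row, r) in enumerate(zip(rec.data, phys)):
        if row.max() > r or row.min() < -r:
            raise ValueError(
                f"channel {rec.channels[i].label!r} exceeds the ±{r} µV "
                "physical range; widen physical_range"
            )
        # map [-r, r] onto the full digital span
        digital[i] = np.round((row + r) / (2 * r) * 65535 - 32768).astype(np.int16)

    for k in range(n_records):
        sl = slice(k * spr, (k + 1) * spr)
        for i in range(n_sig):
            buf.write(struct.pack(f"<{spr}h", *digital[i, sl]))

    Path(path).write_bytes(buf.getvalue())


# ---------------------------------------------------------------------------
# Hypnograms
# ---------------------------------------------------------------------------

def read_hypnogram(path) -> Hypnogram:
    """Parse the plain-text hypnogram dialect.

    Header lines are ``key=value`` (``epoch_s``, ``lights_off``,
    ``lights_on``); every other non-empty line is one stage token.  ``N3``
    is accepted as an alias of ``SWS``.
    """
    epoch_s, lights_off, lights_on = 30.0, 0.0, None
    stages: list[str] = []
    for lineno, raw_line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw_line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" in line:
            key, _, val = line.partition("=")
            key = key.strip()
            try:
                fval = float(val)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: bad header value {val!r}") from None
            if key == "epoch_s":
                epoch_s = fval
            elif key == "lights_off":
                lights_off = fval
            elif key == "lights_on":
                lights_on = fval
            else:
                raise FormatError(f"{path}:{lineno}: unknown header key {key!r}")
            continue
        token = STAGE_ALIASES.get(line, line)
        if token not in STAGES:
            raise FormatError(f"{path}:{lineno}: unknown stage token {line!r}")
        stages.append(token)
    return Hypnogram(stages, epoch_s=epoch_s, lights_off=lights_off, lights_on=lights_on)


def write_hypnogram(h: Hypnogram, path) -> None:
    lines = [
        f"epoch_s={h.epoch_s:g}",
        f"lights_off={h.lights_off:g}",
        f"lights_on={h.lights_on:g}",
    ]
    lines.extend(h.stages)
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Event tables and annotations
# ---------------------------------------------------------------------------

_EVENT_FORMATS = {
    "onset_s": "%.3f",
    "offset_s": "%.3f",
    "trough_s": "%.3f",
    "amplitude_uv": "%.3f",
    "duration_s": "%.3f",
    "core_freq_hz": "%.3f",
    "slope_uv_per_s": "%.3f",
}


def write_events(ev: EventList, path) -> None:
    """Write the event table as CSV (times at ms precision)."""
    df = ev.to_frame()
    for col, fmt in _EVENT_FORMATS.items():
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else fmt % v)
    df.to_csv(path, index=False)


def read_events(path) -> EventList:
    df = pd.read_csv(path)
    events = []
    for _, r in df.iterrows():
        events.append(
            SleepEvent(
                kind=r["kind"],
                channel=r["channel"],
                onset=float(r["onset_s"]),
                offset=float(r["offset_s"]),
                trough_time=float(r["trough_s"]) if pd.notna(r["trough_s"]) else np.nan,
                amplitude=float(r["amplitude_uv"]) if pd.notna(r["amplitude_uv"]) else np.nan,
                core_frequency=float(r["core_freq_hz"]) if pd.notna(r["core_freq_hz"]) else np.nan,
                slope=float(r["slope_uv_per_s"]) if pd.notna(r["slope_uv_per_s"]) else np.nan,
            )
        )
    return EventList(events)


def read_arousals(path) -> pd.DataFrame:
    """Read an arousal annotation CSV with columns onset_s, duration_s."""
    df = pd.read_csv(path)
    missing = {"onset_s", "duration_s"} - set(df.columns)
    if missing:
        raise FormatError(f"arousal file {path} lacks column(s) {sorted(missing)}")
    return df[["onset_s", "duration_s"]].astype(float)
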