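"""Referencing, zero-phase band-pass filtering and automatic artifact masking.

The artifact rule is amplitude-based: any sample where the 10–80 Hz EMG
leaves ±50 µV, or the 0.3–33 Hz EEG leaves ±300 µV, poisons the surrounding
±3 s.  The mask is sample-resolved; a whole-epoch variant is available via
``epoch_resolved=True``.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .core_io import ArtifactMask, Recording, merge_intervals

__all__ = [
    "FilterSpec",
    "ArtifactConfig",
    "rereference",
    "bandpass",
    "bandpass_array",
    "detect_artifacts",
]

#: Acquisition-style band edges per channel kind (Hz).
EEG_BAND = (0.3, 35.0)
EMG_BAND = (10.0, 100.0)


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase Butterworth band-pass specification."""

    low_hz: float
    high_hz: float
    order: int = 4

    def __post_init__(self):
        if not 0 <= self.low_hz < self.high_hz:
            raise ValueError("band edges must satisfy 0 <= low < high")


@dataclass(frozen=True)
class ArtifactConfig:
    eeg_uv: float = 300.0
    emg_uv: float = 50.0
    pad_s: float = 3.0
    eeg_band: tuple[float, float] = (0.3, 33.0)
    emg_band: tuple[float, float] = (10.0, 80.0)
    epoch_resolved: bool = False
    epoch_s: float = 30.0


def _sos(spec: FilterSpec, rate: float):
    nyq = rate / 2.0
    if spec.high_hz >= nyq:
        raise ValueError(f"band edge {spec.high_hz} Hz >= Nyquist {nyq} Hz")
    if spec.low_hz <= 0:
        return signal.butter(spec.order, spec.high_hz / nyq, btype="low", output="sos")
    return signal.butter(
        spec.order, [spec.low_hz / nyq, spec.high_hz / nyq], btype="band", output="sos"
    )


def bandpass_array(x: np.ndarray, spec: FilterSpec, rate: float) -> np.ndarray:
    """Forward-backward (zero-phase) Butterworth band-pass of a 1-D/2-D array."""
    return signal.sosfiltfilt(_sos(spec, rate), x, axis=-1)


def rereference(rec: Recording, scheme: str = "linked-mastoid") -> Recording:
    """Re-reference EEG channels to the average mastoid potential.

    Every EEG channel gets ``mean(M1, M2)`` subtracted; EOG/EMG/ECG are left
    untouched.  The mastoid channels themselves are dropped from the output.
    """
    if scheme != "linked-mastoid":
        raise ValueError(f"unknown reference scheme {scheme!r}")
    if rec.reference == "linked-mastoid":
        return rec
    labels = rec.labels
    for m in ("M1", "M2"):
        if m not in labels:
            raise ValueError(f"mastoid channel {m} missing; cannot re-reference")
    mastoid = 0.5 * (rec.get("M1") + rec.get("M2"))
    keep, data = [], []
    for ch, row in zip(rec.channels, rec.data):
        if ch.label in ("M1", "M2"):
            continue
        keep.append(ch)
        data.append(row - mastoid if ch.kind == "EEG" else row)
    return replace(
        rec, data=np.array(data), channels=keep, reference="linked-mastoid"
    )


def bandpass(
    rec: Recording, spec: FilterSpec, channels: list[str] | None = None
) -> Recording:
    """Zero-phase band-pass selected channels (default: all) of a recording."""
    data = rec.data.copy()
    labels = channels if channels is not None else rec.labels
    for label in labels:
        i = rec.channel_index(label)
        data[i] = bandpass_array(data[i], spec, rec.rate)
    return replace(rec, data=data)


def default_bandpass(rec: Recording) -> Recording:
    """Acquisition-style filtering: EEG/EOG 0.3–35 Hz, EMG 10–100 Hz (ECG untouched)."""
    data = rec.data.copy()
    hi_emg = min(EMG_BAND[1], 0.45 * rec.rate)  # keep edge below Nyquist
    for i, ch in enumerate(rec.channels):
        if ch.kind in ("EEG", "EOG"):
            data[i] = bandpass_array(data[i], FilterSpec(*EEG_BAND), rec.rate)
        elif ch.kind == "EMG":
            data[i] = bandpass_array(data[i], FilterSpec(EMG_BAND[0], hi_emg), rec.rate)
    return replace(rec, data=data)


def detect_artifacts(rec: Recording, config: ArtifactConfig | None = None) -> ArtifactMask:
    """Flag ±pad_s around every supra-threshold EMG/EEG sample.

    Thresholds follow the stated exclusion rule: EMG (10–80 Hz) outside
    ±50 µV or EEG (0.3–33 Hz) outside ±300 µV.  Returns a per-channel mask
    whose global union downstream stages intersect with analysis windows.
    """
    cfg = config or ArtifactConfig()
    per_channel: dict[str, np.ndarray] = {}
    hi_emg = min(cfg.emg_band[1], 0.45 * rec.rate)
    for ch, row in zip(rec.channels, rec.data):
        if ch.kind == "EEG":
            filt = bandpass_array(row, FilterSpec(*cfg.eeg_band), rec.rate)
            thresh = cfg.eeg_uv
        elif ch.kind == "EMG":
            filt = bandpass_array(row, FilterSpec(cfg.emg_band[0], hi_emg), rec.rate)
            thresh = cfg.emg_uv
        else:
            continue
        bad = np.flatnonzero(np.abs(filt) > thresh)
        if bad.size == 0:
            continue
        t = bad / rec.rate
        iv = np.column_stack([t - cfg.pad_s, t + 1.0 / rec.rate + cfg.pad_s])
        iv = np.clip(iv, 0.0, rec.duration)
        if cfg.epoch_resolved:
            iv[:, 0] = np.floor(iv[:, 0] / cfg.epoch_s) * cfg.epoch_s
            iv[:, 1] = np.ceil(iv[:, 1] / cfg.epoch_s) * cfg.epoch_s
        per_channel[ch.label] = merge_intervals(iv)
    return ArtifactMask(per_channel)
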