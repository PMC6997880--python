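"""NREM event detectors: spindles, slow oscillations, AASM-style slow waves.

All detectors share the same skeleton: band-pass the (re-referenced)
signal, derive candidates, threshold them with statistics computed per
night and per channel over artifact-free N2+SWS, and emit
:class:`~somnarch.core_io.SleepEvent` records.

Spindles are marked by a single amplitude criterion — the 0.2-s moving-RMS
envelope of the band-filtered signal exceeding 1.5 standard deviations of
that filtered signal.  Slow oscillations are full 0.5–1.11 Hz cycles
(positive-to-negative zero crossing, down-state trough, up-state peak,
terminal positive-to-negative crossing) kept when both trough-to-peak
amplitude and negative-peak magnitude exceed 1.25x their candidate means.
The AASM-tailored slow-wave detector uses absolute bounds instead
(0.5–2 Hz durations, 75–400 µV) on four derivations, prunes >3-SD
outliers, and classifies a 30-s epoch as "estimated SWS" when the
derivation-averaged summed slow-wave duration exceeds 6 s (20% of the
epoch), mirroring the visual scoring rule.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .core_io import (
    ArtifactMask,
    EventList,
    Hypnogram,
    Recording,
    SleepEvent,
)
from .preprocess import FilterSpec, bandpass_array

__all__ = [
    "DetectorConfig",
    "SlowWaveEstimate",
    "detect_spindles",
    "detect_slow_oscillations",
    "detect_slow_waves_aasm",
    "estimate_sws_epochs",
]

EEG_DERIVATIONS = ("F3", "F4", "C3", "C4")


@dataclass(frozen=True)
class DetectorConfig:
    """Thresholds and bands for all event detectors (units noted per field)."""

    slow_spindle_band: tuple[float, float] = (9.0, 12.0)  # Hz
    fast_spindle_band: tuple[float, float] = (12.0, 15.0)  # Hz
    spindle_threshold_sd: float = 1.5  # SD units of the band-filtered signal
    spindle_dur_range: tuple[float, float] = (0.5, 3.0)  # s
    spindle_merge_gap_s: float = 0.25
    spindle_rms_window_s: float = 0.2
    so_band: tuple[float, float] = (0.5, 1.11)  # Hz
    so_dur_range: tuple[float, float] = (0.9, 2.0)  # s (full cycle)
    so_criterion_factor: float = 1.25  # x mean amplitude / neg-peak
    sw_band: tuple[float, float] = (0.5, 2.0)  # Hz
    sw_dur_range: tuple[float, float] = (0.5, 2.0)  # s <-> 0.5-2 Hz cycles
    sw_amp_range: tuple[float, float] = (75.0, 400.0)  # µV trough-to-peak
    #: sampling allowance on the absolute amplitude bounds: the sampled
    #: extremum of a wave sitting exactly on a bound falls a fraction of a
    #: microvolt short of the continuous value
    amp_tolerance_uv: float = 0.5
    outlier_sd: float = 3.0  # slow-wave pruning
    sws_epoch_threshold_s: float = 6.0  # strict ">" for estimated SWS
    stages: tuple[str, ...] = ("N2", "SWS")  # eligible stages
    filter_order: int = 4
    #: SO/slow-wave detection filter.  The target frequency ranges (0.5-1.11
    #: Hz for SO, 0.5-2 Hz for slow waves) are enforced through the cycle
    #: DURATION windows; filtering itself uses this broader slow band, since
    #: band-passing a single cycle at its own width rings and splits one
    #: wave into several candidates.  0.16-4 Hz is the classic slow-wave
    #: detection band; its gentle high-pass also keeps the trough time
    #: faithful (a steeper one drags extrema toward the cycle centre)
    slow_filter_band: tuple[float, float] = (0.16, 4.0)
    slow_filter_order: int = 2
    #: the AASM slow-wave detector needs sharper zero-crossing localisation
    #: than SO detection (its epoch sums are duration-based), so it filters
    #: slightly wider
    sw_filter_band: tuple[float, float] = (0.16, 8.0)
    #: drop spindle events whose measured core frequency falls outside the
    #: detection band; a band-passed tone keeps its own frequency, so this
    #: cleanly rejects leakage from the neighbouring spindle class
    spindle_require_core_in_band: bool = True
    #: attribute a spindle to the band whose envelope dominates at the event
    #: anchor; a burst just across the 12 Hz border leaks transient energy
    #: into the neighbouring band, but never more than into its own
    spindle_band_attribution: bool = True

    def spindle_band(self, which: str) -> tuple[float, float]:
        if which == "slow":
            return self.slow_spindle_band
        if which == "fast":
            return self.fast_spindle_band
        raise ValueError(f"spindle band must be 'slow' or 'fast', got {which!r}")


class NoDataError(RuntimeError):
    """No artifact-free eligible-stage signal to compute thresholds from."""


# ---------------------------------------------------------------------------
# Shared helpers
# ---------------------------------------------------------------------------

def _eligible_mask(
    rec: Recording, mask: ArtifactMask | None, h: Hypnogram, stages
) -> np.ndarray:
    stage_m = h.sample_mask(stages, rec.rate, rec.n_samples)
    clean = (
        (mask or ArtifactMask.empty()).clean_sample_mask(rec.rate, rec.n_samples)
    )
    return stage_m & clean


def _runs(flag: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True values."""
    d = np.diff(flag.astype(np.int8), prepend=0, append=0)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def _merge_runs(runs, gap: int):
    out = []
    for a, b in runs:
        if out and a - out[-1][1] < gap:
            out[-1][1] = b
        else:
            out.append([a, b])
    return [(a, b) for a, b in out]


def _zero_crossings(x: np.ndarray, rate: float):
    """Interpolated positive-to-negative and negative-to-positive crossing times."""
    pos = x > 0
    p2n_idx = np.flatnonzero(pos[:-1] & ~pos[1:])
    n2p_idx = np.flatnonzero(~pos[:-1] & pos[1:])

    def interp(idx):
        x0, x1 = x[idx], x[idx + 1]
        frac = np.where(x1 != x0, x0 / (x0 - x1), 0.5)
        return (idx + frac) / rate

    return interp(p2n_idx), interp(n2p_idx)


@dataclass
class _Candidate:
    onset: float  # p2n crossing opening the cycle
    offset: float  # terminal p2n crossing
    trough_idx: int
    peak_idx: int
    n2p_time: float  # up-state onset between trough and peak


def _cycle_candidates(
    filt: np.ndarray, rate: float, dur_range: tuple[float, float]
) -> list[_Candidate]:
    """Full negative-then-positive half-wave cycles between p2n crossings."""
    p2n, n2p = _zero_crossings(filt, rate)
    out: list[_Candidate] = []
    j = 0
    for t0, t1 in zip(p2n[:-1], p2n[1:]):
        dur = t1 - t0
        if not dur_range[0] <= dur <= dur_range[1]:
            continue
        while j < len(n2p) and n2p[j] <= t0:
            j += 1
        if j >= len(n2p) or n2p[j] >= t1:
            continue  # no up-state onset inside the cycle
        mid = n2p[j]
        a, m, b = int(t0 * rate), int(mid * rate) + 1, int(t1 * rate) + 1
        neg = filt[a:m]
        pos = filt[m - 1 : b]
        if neg.size == 0 or pos.size == 0:
            continue
        out.append(
            _Candidate(
                onset=t0,
                offset=t1,
                trough_idx=a + int(np.argmin(neg)),
                peak_idx=m - 1 + int(np.argmax(pos)),
                n2p_time=mid,
            )
        )
    return out


def _core_frequency(seg: np.ndarray, rate: float, dur: float) -> float:
    """Oscillation frequency from zero crossings of the filtered segment.

    Uses the median inter-crossing half-period, which is robust to the
    noise-dominated edges of a supra-threshold run; falls back to the
    crossing count for very short segments.
    """
    zc = np.flatnonzero(np.diff(seg > 0))
    if zc.size >= 4:
        half = np.median(np.diff(zc)) / rate
        if half > 0:
            return float(1.0 / (2.0 * half))
    return zc.size / (2.0 * dur)


# ---------------------------------------------------------------------------
# Spindles
# ---------------------------------------------------------------------------

def detect_spindles(
    rec: Recording,
    mask: ArtifactMask | None,
    h: Hypnogram,
    band: str = "fast",
    channels: list[str] | None = None,
    config: DetectorConfig | None = None,
) -> EventList:
    """Detect slow or fast spindles with the single 1.5-SD envelope criterion.

    Per channel: band-pass, form the 0.2-s moving-RMS envelope, threshold at
    1.5 x SD of the band-filtered signal over artifact-free N2+SWS, merge
    supra-threshold runs closer than 0.25 s, and keep runs lasting 0.5–3 s.
    The event anchor (``peak_time``) is the envelope maximum.  Density uses
    artifact-free N2 minutes as denominator.
    """
    cfg = config or DetectorConfig()
    if rec.rate < 200:
        raise ValueError("spindle detection needs rate >= 200 Hz")
    channels = channels or rec.labels_of_kind("EEG")
    lo, hi = cfg.spindle_band(band)
    kind = f"{band}_spindle"
    elig = _eligible_mask(rec, mask, h, cfg.stages)
    if not elig.any():
        raise NoDataError("no artifact-free N2/SWS signal")
    clean = (mask or ArtifactMask.empty()).clean_sample_mask(rec.rate, rec.n_samples)
    win = max(int(round(cfg.spindle_rms_window_s * rec.rate)), 1)
    gap = int(round(cfg.spindle_merge_gap_s * rec.rate))
    other = cfg.spindle_band("slow" if band == "fast" else "fast")
    events: list[SleepEvent] = []
    for label in channels:
        filt = bandpass_array(
            rec.get(label), FilterSpec(lo, hi, cfg.filter_order), rec.rate
        )
        sd = filt[elig].std()
        thresh = cfg.spindle_threshold_sd * sd
        env = np.sqrt(uniform_filter1d(filt**2, size=win, mode="nearest"))
        companion_env = None
        if cfg.spindle_band_attribution:
            cfilt = bandpass_array(
                rec.get(label), FilterSpec(*other, cfg.filter_order), rec.rate
            )
            companion_env = np.sqrt(
                uniform_filter1d(cfilt**2, size=win, mode="nearest")
            )
        runs = _merge_runs(_runs(env > thresh), gap)
        for a, b in runs:
            dur = (b - a) / rec.rate
            if not cfg.spindle_dur_range[0] <= dur <= cfg.spindle_dur_range[1]:
                continue
            seg = filt[a:b]
            trough = a + int(np.argmin(seg))
            if not elig[trough]:
                continue
            if not clean[a : b].all():
                continue
            core = _core_frequency(seg, rec.rate, dur)
            if cfg.spindle_require_core_in_band and not lo <= core <= hi:
                continue
            peak_env = a + int(np.argmax(env[a:b]))
            if companion_env is not None and companion_env[peak_env] > env[peak_env]:
                continue
            events.append(
                SleepEvent(
                    kind=kind,
                    channel=label,
                    onset=a / rec.rate,
                    offset=b / rec.rate,
                    trough_time=trough / rec.rate,
                    peak_time=peak_env / rec.rate,
                    amplitude=float(seg.max() - seg.min()),
                    core_frequency=core,
                )
            )
    n2_min = (
        _eligible_mask(rec, mask, h, ("N2",)).sum() / rec.rate / 60.0
    )
    return EventList(
        events,
        provenance=f"spindle[{band} {lo}-{hi} Hz, {cfg.spindle_threshold_sd} SD]",
        denominator_min=n2_min if n2_min > 0 else None,
    )


# ---------------------------------------------------------------------------
# Slow oscillations
# ---------------------------------------------------------------------------

def detect_slow_oscillations(
    rec: Recording,
    mask: ArtifactMask | None,
    h: Hypnogram,
    channels: list[str] | None = None,
    config: DetectorConfig | None = None,
) -> EventList:
    """Detect slow oscillations with the relative x1.25 amplitude criterion.

    Candidates are full 0.5–1.11 Hz cycles of 0.9–2.0 s; a candidate is
    kept when its trough-to-peak amplitude AND its negative-peak magnitude
    both reach 1.25x the respective candidate means of that channel.
    ``offset`` is the terminal positive-to-negative zero crossing (end of
    the up-state), which anchors the coupling window downstream.
    """
    cfg = config or DetectorConfig()
    channels = channels or rec.labels_of_kind("EEG")
    elig = _eligible_mask(rec, mask, h, cfg.stages)
    events: list[SleepEvent] = []
    for label in channels:
        filt = bandpass_array(
            rec.get(label),
            FilterSpec(*cfg.slow_filter_band, cfg.slow_filter_order),
            rec.rate,
        )
        cands = [
            c
            for c in _cycle_candidates(filt, rec.rate, cfg.so_dur_range)
            if elig[c.trough_idx]
        ]
        if not cands:
            continue
        amps = np.array([filt[c.peak_idx] - filt[c.trough_idx] for c in cands])
        negs = np.array([-filt[c.trough_idx] for c in cands])
        amp_cut = cfg.so_criterion_factor * amps.mean()
        neg_cut = cfg.so_criterion_factor * negs.mean()
        for c, amp, neg in zip(cands, amps, negs):
            if amp < amp_cut or neg < neg_cut:
                continue
            t_trough = c.trough_idx / rec.rate
            dur = c.offset - c.onset
            events.append(
                SleepEvent(
                    kind="so",
                    channel=label,
                    onset=c.onset,
                    offset=c.offset,
                    trough_time=t_trough,
                    peak_time=c.peak_idx / rec.rate,
                    amplitude=float(amp),
                    core_frequency=1.0 / dur,
                    slope=float(neg / (c.n2p_time - t_trough)),
                )
            )
    denom = elig.sum() / rec.rate / 60.0
    return EventList(
        events,
        provenance=f"so[{cfg.so_band[0]}-{cfg.so_band[1]} Hz, x{cfg.so_criterion_factor}]",
        denominator_min=denom if denom > 0 else None,
    )


# ---------------------------------------------------------------------------
# AASM-tailored slow waves and estimated SWS
# ---------------------------------------------------------------------------

def detect_slow_waves_aasm(
    rec: Recording,
    mask: ArtifactMask | None,
    h: Hypnogram,
    channels: tuple[str, ...] = EEG_DERIVATIONS,
    config: DetectorConfig | None = None,
    exclude_outliers: bool = True,
) -> tuple[EventList, pd.DataFrame]:
    """Detect AASM-definition slow waves on the four scoring derivations.

    Candidates follow the SO cycle grammar but with 0.5–2 s durations and an
    absolute 75–400 µV trough-to-peak amplitude window.  Amplitude is read
    from the broadband signal at the band-filtered extrema, so the absolute
    bounds are not biased by filter attenuation.  Detection runs per
    derivation; with ``exclude_outliers`` events whose duration, frequency
    or amplitude deviates more than 3 SD from the channel mean are pruned.
    Returns the events plus a per-epoch table of summed slow-wave duration
    per channel and their across-derivation mean.
    """
    cfg = config or DetectorConfig()
    missing = [c for c in channels if c not in rec.labels]
    if missing:
        raise ValueError(f"missing derivation channel(s): {missing}")
    elig = _eligible_mask(rec, mask, h, cfg.stages)
    per_channel_events: dict[str, list[SleepEvent]] = {}
    for label in channels:
        raw = rec.get(label)
        filt = bandpass_array(
            raw,
            FilterSpec(*cfg.sw_filter_band, cfg.slow_filter_order),
            rec.rate,
        )
        found = []
        for c in _cycle_candidates(filt, rec.rate, cfg.sw_dur_range):
            if not elig[c.trough_idx]:
                continue
            # amplitude read from the broadband signal at the band-located
            # extrema, so absolute bounds are not biased by filter
            # attenuation; bounds carry a 0.5 µV allowance for the sampled
            # extremum sitting marginally below the continuous one
            amp = raw[c.peak_idx] - raw[c.trough_idx]
            lo_a = cfg.sw_amp_range[0] - cfg.amp_tolerance_uv
            hi_a = cfg.sw_amp_range[1] + cfg.amp_tolerance_uv
            if not lo_a <= amp <= hi_a:
                continue
            dur = c.offset - c.onset
            t_trough = c.trough_idx / rec.rate
            found.append(
                SleepEvent(
                    kind="slow_wave",
                    channel=label,
                    onset=c.onset,
                    offset=c.offset,
                    trough_time=t_trough,
                    peak_time=c.peak_idx / rec.rate,
                    amplitude=float(amp),
                    core_frequency=1.0 / dur,
                    slope=float(-filt[c.trough_idx] / (c.n2p_time - t_trough)),
                )
            )
        if exclude_outliers and len(found) >= 3:
            feats = np.array(
                [[e.duration, e.core_frequency, e.amplitude] for e in found]
            )
            mu = feats.mean(axis=0)
            sd = feats.std(axis=0, ddof=0)
            sd[sd == 0] = np.inf
            keep = (np.abs(feats - mu) <= cfg.outlier_sd * sd).all(axis=1)
            found = [e for e, k in zip(found, keep) if k]
        per_channel_events[label] = found

    # per-epoch summed duration per derivation, then the cross-derivation mean
    table = pd.DataFrame(
        0.0, index=range(h.n_epochs), columns=list(channels)
    )
    for label, evs in per_channel_events.items():
        for e in evs:
            ep = h.epoch_of(e.trough_time)  # tie-break: epoch holding the trough
            if 0 <= ep < h.n_epochs:
                table.loc[ep, label] += e.duration
    table["mean"] = table[list(channels)].mean(axis=1)
    table.insert(0, "stage", list(h.stages))
    table.index.name = "epoch_idx"

    denom = elig.sum() / rec.rate / 60.0
    all_events = [e for evs in per_channel_events.values() for e in evs]
    return (
        EventList(
            all_events,
            provenance="slow_wave[aasm 0.5-2 Hz, 75-400 uV]",
            denominator_min=denom if denom > 0 else None,
        ),
        table,
    )


@dataclass
class SlowWaveEstimate:
    """Estimated-SWS classification derived from summed slow-wave durations."""

    flags: pd.Series  # per-epoch bool, True = epoch estimates SWS
    estimated_sws_min: float
    density_per_nrem_min: float | None = None  # events per derivation per min


def estimate_sws_epochs(
    epoch_durations: pd.DataFrame,
    h: Hypnogram,
    events: EventList | None = None,
    n_derivations: int = len(EEG_DERIVATIONS),
    config: DetectorConfig | None = None,
) -> SlowWaveEstimate:
    """Flag N2/SWS epochs whose mean summed slow-wave duration exceeds 6 s.

    The threshold is strict (exactly 6.0 s is NOT estimated SWS).  When the
    slow-wave :class:`EventList` is supplied, the per-derivation slow-wave
    density per artifact-free NREM minute is reported alongside.
    """
    cfg = config or DetectorConfig()
    scored = pd.Series(
        [s in cfg.stages for s in h.stages], index=epoch_durations.index
    )
    flags = (epoch_durations["mean"] > cfg.sws_epoch_threshold_s) & scored
    est_min = float(flags.sum()) * h.epoch_s / 60.0
    density = None
    if events is not None and events.denominator_min:
        density = len(events) / n_derivations / events.denominator_min
    return SlowWaveEstimate(
        flags=flags, estimated_sws_min=est_min, density_per_nrem_min=density
    )
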