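"""Orchestration: per-night processing, per-subject averaging, group reports.

``run_night`` composes the full chain for one recording + hypnogram pair
(re-reference, filter, artifact mask, PSD, detectors, coupling, macro), and
``compare_groups`` produces a table of two-group statistics over
subject-level variables.  ``simulate_cohort`` renders synthetic cohorts
with controllable group contrasts for power/calibration experiments.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .core_io import ArtifactMask, EventList, Hypnogram, Recording
from .coupling import CouplingSummary, couple_so_spindles
from .detectors import (
    DetectorConfig,
    SlowWaveEstimate,
    detect_slow_oscillations,
    detect_slow_waves_aasm,
    detect_spindles,
    estimate_sws_epochs,
)
from .detectors import NoDataError as DetectorNoData
from .macro import MacroSummary, StabilitySummary, summarize_macro, summarize_stability
from .preprocess import ArtifactConfig, default_bandpass, detect_artifacts, rereference
from .spectra import NoDataError, PSDResult, band_power, welch_psd
from .stats import compare_variable
from .synthetic_psg import (
    EventSpec,
    KindSpec,
    NoiseSpec,
    default_event_spec,
    generate_hypnogram,
    generate_recording,
)

__all__ = [
    "PipelineConfig",
    "NightResult",
    "run_night",
    "aggregate_subject",
    "compare_groups",
    "simulate_cohort",
]

ANALYSIS_CHANNELS = ("F3", "F4", "C3", "C4", "P3", "P4")
SWA_BAND = (2.0, 3.2)  # Hz, slow-wave activity


@dataclass(frozen=True)
class PipelineConfig:
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    artifact: ArtifactConfig = field(default_factory=ArtifactConfig)
    psd_stages: tuple[str, ...] = ("N2", "SWS")
    channels: tuple[str, ...] = ANALYSIS_CHANNELS
    coupling_channel: str = "C4"
    n_boot: int = 1000
    seed: int = 0

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


@dataclass
class NightResult:
    """Everything computed from one recording + hypnogram pair."""

    macro: MacroSummary
    stability: StabilitySummary
    psd: PSDResult | None
    events: dict[str, EventList]
    coupling: CouplingSummary | None
    sw_estimate: SlowWaveEstimate | None
    qc: dict
    config_hash: str

    def variables(self) -> dict[str, float | None]:
        """Flat scalar variables used for subject averaging and group tests."""
        out: dict[str, float | None] = {}
        out.update(self.macro.as_dict())
        out.update(self.stability.as_dict())
        for kind in ("fast_spindle", "slow_spindle", "so"):
            ev = self.events.get(kind)
            if ev is not None and ev.denominator_min:
                chans = {e.channel for e in ev} or set()
                if chans:
                    dens = [ev.density_per_min(c) for c in sorted(chans)]
                    out[f"{kind}_density_per_min"] = float(np.mean(dens))
                else:
                    out[f"{kind}_density_per_min"] = 0.0
                out[f"{kind}_amplitude_uv"] = (
                    float(np.mean([e.amplitude for e in ev])) if len(ev) else None
                )
                out[f"{kind}_duration_s"] = (
                    float(np.mean([e.duration for e in ev])) if len(ev) else None
                )
        if self.sw_estimate is not None:
            out["estimated_sws_min"] = self.sw_estimate.estimated_sws_min
            out["slow_wave_density_per_nrem_min"] = (
                self.sw_estimate.density_per_nrem_min
            )
        if self.coupling is not None and len(self.coupling.per_channel):
            pc = self.coupling.per_channel
            out["coupling_n"] = float(pc["n_coupled"].sum())
            out["coupling_mean_delay_s"] = (
                float(pc["mean_delay_s"].mean()) if pc["n_coupled"].sum() else None
            )
            out["coupling_delay_sd_s"] = (
                float(pc["delay_sd_s"].mean())
                if np.isfinite(pc["delay_sd_s"]).any()
                else None
            )
            out["coupled_so_dur_s"] = (
                float(pc["coupled_so_dur_s"].mean())
                if np.isfinite(pc["coupled_so_dur_s"]).any()
                else None
            )
        if self.psd is not None:
            swa = band_power(self.psd, *SWA_BAND)
            out["swa_power_uv2"] = float(np.mean(swa))
        return out


def run_night(
    rec: Recording,
    h: Hypnogram,
    arousals: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
    extra_mask: ArtifactMask | None = None,
) -> NightResult:
    """Run the whole per-night analysis chain deterministically.

    Raw recordings are linked-mastoid re-referenced when M1/M2 are present;
    an optional human-override mask is merged into the automatic one.  A
    missing-data PSD (e.g. an all-wake night) is recorded as a QC flag,
    never an exception.
    """
    cfg = config or PipelineConfig()
    qc: dict = {}
    if rec.reference != "linked-mastoid" and {"M1", "M2"} <= set(rec.labels):
        rec = rereference(rec)
    mask = detect_artifacts(rec, cfg.artifact)
    if extra_mask is not None:
        mask = mask.merged_with(extra_mask)
    qc["artifact_masked_min"] = mask.masked_seconds() / 60.0
    filtered = default_bandpass(rec)
    channels = [c for c in cfg.channels if c in rec.labels]

    psd = None
    try:
        psd = welch_psd(filtered, mask, h, stages=cfg.psd_stages, channels=channels)
        qc["psd_n_windows"] = psd.n_windows
    except NoDataError as exc:
        qc["psd_no_data"] = str(exc)

    events: dict[str, EventList] = {}
    coupling = None
    sw_est = None
    try:
        events["fast_spindle"] = detect_spindles(
            filtered, mask, h, band="fast", channels=channels, config=cfg.detector
        )
        events["slow_spindle"] = detect_spindles(
            filtered, mask, h, band="slow", channels=channels, config=cfg.detector
        )
        events["so"] = detect_slow_oscillations(
            filtered, mask, h, channels=channels, config=cfg.detector
        )
        sw_events, sw_table = detect_slow_waves_aasm(
            filtered, mask, h, config=cfg.detector
        )
        events["slow_wave"] = sw_events
        sw_est = estimate_sws_epochs(sw_table, h, events=sw_events, config=cfg.detector)
        coupling = couple_so_spindles(events["so"], events["fast_spindle"])
    except Exception as exc:  # no eligible NREM signal etc.
        qc["detector_no_data"] = str(exc)

    return NightResult(
        macro=summarize_macro(h),
        stability=summarize_stability(h, arousals),
        psd=psd,
        events=events,
        coupling=coupling,
        sw_estimate=sw_est,
        qc=qc,
        config_hash=cfg.hash(),
    )


def aggregate_subject(nights: list[dict]) -> tuple[dict, dict]:
    """Arithmetic per-variable mean across nights, skipping missing values.

    ``nights`` is a list of per-night variable dicts; returns the mean dict
    and a per-variable count of contributing nights.
    """
    if not nights:
        raise ValueError("need at least one night")
    keys = sorted({k for n in nights for k in n})
    means, counts = {}, {}
    for k in keys:
        vals = [
            n[k]
            for n in nights
            if k in n and n[k] is not None and np.isfinite(n[k])
        ]
        counts[k] = len(vals)
        means[k] = float(np.mean(vals)) if vals else None
    return means, counts


def compare_groups(
    subjects: pd.DataFrame,
    group_col: str = "group",
    labels: tuple[str, str] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-group statistics for every numeric column of a subject table."""
    groups = list(pd.unique(subjects[group_col]))
    if labels is None:
        if len(groups) != 2:
            raise ValueError(f"expected exactly two groups, found {groups}")
        labels = (groups[0], groups[1])
    a = subjects[subjects[group_col] == labels[0]]
    b = subjects[subjects[group_col] == labels[1]]
    rows = []
    for col in subjects.columns:
        if col == group_col or not pd.api.types.is_numeric_dtype(subjects[col]):
            continue
        xs = a[col].dropna().to_numpy()
        ys = b[col].dropna().to_numpy()
        if xs.size == 0 or ys.size == 0:
            continue
        if xs.size < 2 or ys.size < 2:
            rows.append({"variable": col, "n1": xs.size, "n2": ys.size})
            continue
        rows.append(compare_variable(col, xs, ys, n_boot=n_boot, seed=seed).as_dict())
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Synthetic cohorts
# ---------------------------------------------------------------------------

def _scale_density(spec: KindSpec, factor: float) -> KindSpec:
    return KindSpec(
        density={k: v * factor for k, v in spec.density.items()},
        amp_mean=spec.amp_mean,
        amp_sd=spec.amp_sd,
        amp_range=spec.amp_range,
        dur_range=spec.dur_range,
        freq_range=spec.freq_range,
    )


def patient_like_spec(sw_factor: float = 0.1, coupling_lag_s: float | None = None) -> EventSpec:
    """Default events with slow-wave/SO production scaled down.

    Emulates a cohort producing fewer slow waves (hence little scored SWS)
    while spindles stay intact.
    """
    base = default_event_spec()
    kw = dict(
        slow_spindle=base.slow_spindle,
        fast_spindle=base.fast_spindle,
        so=base.so,
        slow_wave=_scale_density(base.slow_wave, sw_factor),
    )
    if coupling_lag_s is not None:
        kw["coupled_fraction"] = 0.9
        kw["coupling_lag_s"] = coupling_lag_s
    return EventSpec(**kw)


def simulate_subject_night(
    seed: int,
    minutes: float = 20.0,
    stage_mix: dict[str, float] | None = None,
    spec: EventSpec | None = None,
    noise: NoiseSpec | None = None,
    rate: float = 250.0,
    spindle_channel: str = "C4",
    config: DetectorConfig | None = None,
    stickiness: float = 0.7,
) -> dict[str, float]:
    """Generate one synthetic night and run the detector battery on it.

    Returns the scalar variables used in cohort experiments (estimated SWS
    minutes, slow-wave density, spindle/SO densities on one channel, and
    the SO-fast-spindle coupling delay when coupling is enabled).
    """
    stage_mix = stage_mix or {"N1": 0.10, "N2": 0.55, "SWS": 0.15, "REM": 0.15}
    n_epochs = int(round(minutes * 60 / 30.0))
    h = generate_hypnogram(n_epochs, stage_mix, seed=seed, stickiness=stickiness)
    rec, gt = generate_recording(h, spec=spec, noise=noise, seed=seed + 10_000, rate=rate)
    mask = ArtifactMask.empty()
    cfg = config or DetectorConfig()

    out: dict[str, float] = {}
    sw_events, sw_table = detect_slow_waves_aasm(rec, mask, h, config=cfg)
    est = estimate_sws_epochs(sw_table, h, events=sw_events, config=cfg)
    out["estimated_sws_min"] = est.estimated_sws_min
    out["slow_wave_density_per_nrem_min"] = est.density_per_nrem_min or 0.0
    out["true_sws_min"] = h.minutes_in({"SWS"})

    # spindle/SO microarchitecture is an N2 analysis: restricting the
    # threshold statistics to N2 keeps them comparable between subjects
    # with and without slow-wave sleep
    n2_cfg = dataclasses.replace(cfg, stages=("N2",))
    try:
        fast = detect_spindles(rec, mask, h, "fast", [spindle_channel], n2_cfg)
        slow = detect_spindles(rec, mask, h, "slow", [spindle_channel], n2_cfg)
        so = detect_slow_oscillations(rec, mask, h, [spindle_channel], n2_cfg)
    except DetectorNoData:
        # a night without N2 has no spindle/SO analysis: missing, not zero
        for key in (
            "fast_spindle_density_per_min",
            "slow_spindle_density_per_min",
            "so_density_per_min",
        ):
            out[key] = np.nan
        return out
    out["fast_spindle_density_per_min"] = (
        fast.density_per_min() if fast.denominator_min else 0.0
    )
    out["slow_spindle_density_per_min"] = (
        slow.density_per_min() if slow.denominator_min else 0.0
    )
    out["so_density_per_min"] = so.density_per_min() if so.denominator_min else 0.0
    if spec is not None and spec.coupled_fraction > 0:
        summary = couple_so_spindles(so, fast)
        if len(summary.per_channel) and summary.per_channel["n_coupled"].sum() > 0:
            out["coupling_mean_delay_s"] = float(
                summary.per_channel["mean_delay_s"].mean()
            )
    return out


#: stage mixes for the two simulated groups: the patient-like group barely
#: reaches slow-wave sleep (its hallmark), the control mix follows typical
#: older-adult stage fractions
PATIENT_STAGE_MIX = {"N1": 0.18, "N2": 0.62, "SWS": 0.0, "REM": 0.15}
CONTROL_STAGE_MIX = {"N1": 0.12, "N2": 0.55, "SWS": 0.15, "REM": 0.18}


def simulate_cohort(
    n_a: int = 4,
    n_b: int = 10,
    seed: int = 0,
    minutes: float = 20.0,
    spec_a: EventSpec | None = None,
    spec_b: EventSpec | None = None,
    mix_a: dict[str, float] | None = None,
    mix_b: dict[str, float] | None = None,
    **night_kwargs,
) -> pd.DataFrame:
    """Simulate a two-group cohort (one night per subject) and collect variables.

    Group "A" defaults to the patient-like condition — slow-wave production
    scaled to x0.1 and essentially no scored SWS (visual staging cannot call
    SWS without slow waves) — group "B" to the full default spec with a
    normal stage mix.  Spindle and SO parameters are identical in both
    groups.
    """
    spec_a = spec_a or patient_like_spec(0.1)
    spec_b = spec_b or default_event_spec()
    mix_a = mix_a or PATIENT_STAGE_MIX
    mix_b = mix_b or CONTROL_STAGE_MIX
    rows = []
    for i in range(n_a):
        v = simulate_subject_night(
            seed * 1000 + i, minutes, stage_mix=mix_a, spec=spec_a, **night_kwargs
        )
        rows.append({"subject": f"A{i}", "group": "A", **v})
    for i in range(n_b):
        v = simulate_subject_night(
            seed * 1000 + 100 + i, minutes, stage_mix=mix_b, spec=spec_b, **night_kwargs
        )
        rows.append({"subject": f"B{i}", "group": "B", **v})
    return pd.DataFrame(rows)
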