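"""Hypnogram-derived macroarchitecture and stability/fragmentation metrics.

Definitions (all computed between lights-off and lights-on):

* total sleep time (TST): minutes scored N1/N2/SWS/REM;
* sleep efficiency: 100 x TST / time in bed;
* sleep onset: first epoch scored as any sleep stage (AASM convention; a
  persistent-sleep variant is available via ``onset_rule``);
* REM latency: sleep onset to the first REM epoch;
* WASO: wake minutes between sleep onset and lights-on.

Stability metrics follow common clinical operationalisations.  The
"functional uncertainty" and "stability" constructs originate in cited
methodological work whose exact rules are not restated here; the defaults
below (documented per function) are reasonable readings and are pluggable.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import Hypnogram, NREM_STAGES, SLEEP_STAGES

__all__ = ["MacroSummary", "StabilitySummary", "summarize_macro", "summarize_stability"]


@dataclass
class MacroSummary:
    tst_min: float
    sleep_efficiency_pct: float
    latency_sleep_onset_min: float | None
    latency_rem_min: float | None
    waso_min: float
    stage_min: dict[str, float]
    stage_pct: dict[str, float]  # % of TST

    def as_dict(self) -> dict[str, float]:
        out = {
            "tst_min": self.tst_min,
            "sleep_efficiency_pct": self.sleep_efficiency_pct,
            "latency_sleep_onset_min": self.latency_sleep_onset_min,
            "latency_rem_min": self.latency_rem_min,
            "waso_min": self.waso_min,
        }
        for s in ("N1", "N2", "SWS", "REM"):
            out[f"{s.lower()}_min"] = self.stage_min[s]
            out[f"{s.lower()}_pct"] = self.stage_pct[s]
        return out


@dataclass
class StabilitySummary:
    arousal_index_per_h: float | None
    awakening_index_per_h: float
    transitions_per_h: float
    tfu_ratio: float
    wake_sleep_transitions_per_min: float
    stability_nrem_min: float | None
    stability_rem_min: float | None

    def as_dict(self) -> dict[str, float]:
        return {
            "arousal_index_per_h": self.arousal_index_per_h,
            "awakening_index_per_h": self.awakening_index_per_h,
            "transitions_per_h": self.transitions_per_h,
            "tfu_ratio": self.tfu_ratio,
            "wake_sleep_transitions_per_min": self.wake_sleep_transitions_per_min,
            "stability_nrem_min": self.stability_nrem_min,
            "stability_rem_min": self.stability_rem_min,
        }


def _scored_epochs(h: Hypnogram) -> tuple[list[str], float]:
    """Stages of epochs inside the lights window, plus the epoch length (min)."""
    first = int(h.lights_off // h.epoch_s)
    last = int(np.ceil(h.lights_on / h.epoch_s))
    return h.stages[first:last], h.epoch_s / 60.0


def summarize_macro(h: Hypnogram) -> MacroSummary:
    """Macroarchitecture table for one night (minutes, percentages of TST)."""
    stages, ep_min = _scored_epochs(h)
    tib_min = (h.lights_on - h.lights_off) / 60.0
    sleep_flags = [s in SLEEP_STAGES for s in stages]
    tst = sum(sleep_flags) * ep_min
    eff = 100.0 * tst / tib_min if tib_min > 0 else 0.0

    onset_idx = next((i for i, f in enumerate(sleep_flags) if f), None)
    onset_lat = onset_idx * ep_min if onset_idx is not None else None
    rem_idx = next(
        (i for i, s in enumerate(stages) if s == "REM"), None
    )
    rem_lat = (
        (rem_idx - onset_idx) * ep_min
        if (rem_idx is not None and onset_idx is not None)
        else None
    )
    waso = (
        sum(1 for s in stages[onset_idx:] if s == "W") * ep_min
        if onset_idx is not None
        else 0.0
    )
    stage_min = {
        s: sum(1 for x in stages if x == s) * ep_min for s in ("N1", "N2", "SWS", "REM")
    }
    stage_pct = {
        s: (100.0 * m / tst if tst > 0 else 0.0) for s, m in stage_min.items()
    }
    return MacroSummary(
        tst_min=tst,
        sleep_efficiency_pct=eff,
        latency_sleep_onset_min=onset_lat,
        latency_rem_min=rem_lat,
        waso_min=waso,
        stage_min=stage_min,
        stage_pct=stage_pct,
    )


def _run_lengths(flags: list[bool]) -> list[int]:
    """Lengths of maximal runs of True."""
    out, n = [], 0
    for f in flags:
        if f:
            n += 1
        elif n:
            out.append(n)
            n = 0
    if n:
        out.append(n)
    return out


def _functional_uncertainty_epochs(stages: list[str]) -> int:
    """Epochs inside periods of functional uncertainty.

    Default reading: a maximal run of epochs in which every consecutive
    pair differs in stage, containing at least two such changes (three or
    more epochs of continuous instability).  Returns the number of epochs
    covered by such runs.
    """
    changes = [a != b for a, b in zip(stages[:-1], stages[1:])]
    total = 0
    for run in _run_lengths(changes):
        if run >= 2:  # >= 2 consecutive transitions -> run + 1 epochs
            total += run + 1
    return total


def summarize_stability(
    h: Hypnogram, arousals: pd.DataFrame | None = None
) -> StabilitySummary:
    """Stability and fragmentation metrics for one night.

    ``arousals`` is an annotation table with ``onset_s`` (and duration)
    columns; the arousal index is None when it is absent.
    """
    stages, ep_min = _scored_epochs(h)
    sleep_flags = [s in SLEEP_STAGES for s in stages]
    tst_h = sum(sleep_flags) * ep_min / 60.0
    tib_h = (h.lights_on - h.lights_off) / 3600.0

    pairs = list(zip(stages[:-1], stages[1:]))
    n_changes = sum(1 for a, b in pairs if a != b)
    n_awakenings = sum(
        1 for a, b in pairs if a in SLEEP_STAGES and b == "W"
    )
    n_wake_sleep = sum(
        1
        for a, b in pairs
        if (a == "W") != (b == "W") and (a in SLEEP_STAGES or b in SLEEP_STAGES)
    )

    arousal_idx = None
    if arousals is not None:
        in_sleep = 0
        for t in arousals["onset_s"]:
            i = h.epoch_of(float(t))
            if 0 <= i < h.n_epochs and h.stages[i] in SLEEP_STAGES:
                in_sleep += 1
        arousal_idx = in_sleep / tst_h if tst_h > 0 else None

    nrem_runs = _run_lengths([s in NREM_STAGES for s in stages])
    rem_runs = _run_lengths([s == "REM" for s in stages])
    tfu_min = _functional_uncertainty_epochs(stages) * ep_min
    tst_min = tst_h * 60.0

    return StabilitySummary(
        arousal_index_per_h=arousal_idx,
        awakening_index_per_h=n_awakenings / tst_h if tst_h > 0 else 0.0,
        transitions_per_h=n_changes / tib_h if tib_h > 0 else 0.0,
        tfu_ratio=tfu_min / tst_min if tst_min > 0 else 0.0,
        wake_sleep_transitions_per_min=(
            n_wake_sleep / tst_min if tst_min > 0 else 0.0
        ),
        stability_nrem_min=float(np.mean(nrem_runs)) * ep_min if nrem_runs else None,
        stability_rem_min=float(np.mean(rem_runs)) * ep_min if rem_runs else None,
    )
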