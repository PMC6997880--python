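"""Shared fixtures: small synthetic nights and quiet high-SNR scenarios."""
from __future__ import annotations

import numpy as np
import pytest

from somnarch.core_io import ArtifactMask, Channel, Hypnogram, Recording
from somnarch.synthetic_psg import EventSpec, KindSpec, NoiseSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def empty_mask():
    return ArtifactMask.empty()


def quiet_noise() -> NoiseSpec:
    """Low-amplitude background: the high-SNR condition for detector scoring."""
    return NoiseSpec(
        stage_rms={"W": 10.0, "N1": 10.0, "N2": 10.0, "SWS": 12.0, "REM": 10.0, "UNSCORED": 10.0}
    )


def high_snr_spec(
    fast: float = 2.5,
    slow: float = 0.0,
    so: float = 3.5,
    slow_wave: float = 0.0,
    coupled_fraction: float = 0.0,
    coupling_lag_s: float = 0.3,
) -> EventSpec:
    """Event spec with elevated amplitudes for detector-recovery scoring."""
    return EventSpec(
        slow_spindle=KindSpec(
            density={"N2": slow} if slow else {},
            amp_mean=60.0, amp_sd=10.0, amp_range=(20.0, 200.0),
            dur_range=(0.5, 2.0), freq_range=(9.5, 11.5),
        ),
        fast_spindle=KindSpec(
            density={"N2": fast} if fast else {},
            amp_mean=80.0, amp_sd=10.0, amp_range=(20.0, 250.0),
            dur_range=(0.5, 2.0), freq_range=(12.5, 14.5),
        ),
        so=KindSpec(
            density={"N2": so} if so else {},
            amp_mean=220.0, amp_sd=30.0, amp_range=(120.0, 400.0),
            dur_range=(0.9, 2.0),
        ),
        slow_wave=KindSpec(
            density={"N2": slow_wave} if slow_wave else {},
            amp_mean=150.0, amp_sd=50.0, amp_range=(75.0, 400.0),
            dur_range=(0.8, 1.6),
        ),
        coupled_fraction=coupled_fraction,
        coupling_lag_s=coupling_lag_s,
    )


def quiet_recording(
    duration_s: float = 60.0, channels=("C4",), rate: float = 250.0, noise_uv: float = 0.01, seed: int = 0
) -> Recording:
    """Near-silent EEG recording for threshold-behaviour tests."""
    rng = np.random.default_rng(seed)
    n = int(duration_s * rate)
    data = noise_uv * rng.standard_normal((len(channels), n))
    return Recording(
        data, rate, [Channel(c, "EEG" if "EMG" not in c else "EMG") for c in channels],
        reference="linked-mastoid",
    )


def all_stage_hypnogram(stage: str, n_epochs: int) -> Hypnogram:
    return Hypnogram([stage] * n_epochs)


def pink_recording(
    duration_s: float = 120.0, channels=("C4",), rate: float = 250.0,
    rms_uv: float = 10.0, seed: int = 0,
) -> Recording:
    """Realistic 1/f background without any injected events."""
    from somnarch.synthetic_psg import _pink_noise

    rng = np.random.default_rng(seed)
    n = int(duration_s * rate)
    data = np.vstack([rms_uv * _pink_noise(n, 1.0, rng) for _ in channels])
    return Recording(
        data, rate, [Channel(c) for c in channels], reference="linked-mastoid"
    )


def match_f1(detected, truth, tol: float = 0.25) -> float:
    """Greedy one-to-one F1 between detected and true event times."""
    det = sorted(detected)
    used: set[int] = set()
    tp = 0
    for t in sorted(truth):
        for j, d in enumerate(det):
            if j not in used and abs(d - t) <= tol:
                used.add(j)
                tp += 1
                break
    prec = tp / len(det) if det else 0.0
    rec = tp / len(truth) if truth else 0.0
    return 2 * prec * rec / (prec + rec) if prec + rec else 0.0
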