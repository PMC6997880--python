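"""Referencing, zero-phase filtering and the ±3 s artifact exclusion rule."""
import numpy as np
import pytest

from somnarch.core_io import Channel, Recording
from somnarch.preprocess import (
    ArtifactConfig,
    FilterSpec,
    bandpass,
    bandpass_array,
    detect_artifacts,
    rereference,
)
from somnarch.synthetic_psg import generate_recording, inject_artifacts
from somnarch.core_io import Hypnogram


RATE = 250.0


def _rec(rows: dict[str, np.ndarray], kinds: dict[str, str] | None = None) -> Recording:
    kinds = kinds or {}
    chans = [Channel(k, kinds.get(k, "EEG")) for k in rows]
    return Recording(np.vstack(list(rows.values())), RATE, chans)


# --- re-referencing ---------------------------------------------------------

def test_rereference_identity_when_mastoids_are_zero(rng):
    x = rng.standard_normal(1000)
    rec = _rec({"C3": x, "M1": np.zeros(1000), "M2": np.zeros(1000)})
    out = rereference(rec)
    assert np.allclose(out.get("C3"), x)
    assert out.reference == "linked-mastoid"
    assert "M1" not in out.labels


def test_rereference_subtracts_constant_offset(rng):
    x = rng.standard_normal(1000)
    c = 7.5
    rec = _rec({"C3": x, "M1": np.full(1000, c), "M2": np.full(1000, c)})
    out = rereference(rec)
    assert np.allclose(out.get("C3"), x - c)


def test_rereference_matches_per_sample_arithmetic(rng):
    rows = {k: rng.standard_normal(500) for k in ("F3", "C3", "P3", "M1", "M2", "EMG")}
    rec = _rec(rows, kinds={"EMG": "EMG"})
    out = rereference(rec)
    mast = 0.5 * (rows["M1"] + rows["M2"])
    for ch in ("F3", "C3", "P3"):
        assert np.allclose(out.get(ch), rows[ch] - mast)
    assert np.allclose(out.get("EMG"), rows["EMG"])  # EMG untouched


def test_rereference_requires_mastoids(rng):
    rec = _rec({"C3": rng.standard_normal(100)})
    with pytest.raises(ValueError, match="mastoid"):
        rereference(rec)


# --- filtering --------------------------------------------------------------

def test_passband_tone_amplitude_preserved():
    t = np.arange(int(20 * RATE)) / RATE
    x = np.sin(2 * np.pi * 10.0 * t)
    y = bandpass_array(x, FilterSpec(0.3, 35.0), RATE)
    mid = slice(int(5 * RATE), int(15 * RATE))
    assert abs(y[mid].max() - 1.0) < 0.05


def test_slow_drift_strongly_attenuated():
    t = np.arange(int(120 * RATE)) / RATE
    x = np.sin(2 * np.pi * 0.05 * t)
    y = bandpass_array(x, FilterSpec(0.3, 35.0), RATE)
    assert np.abs(y).max() < 0.1  # >= 90% attenuation


def test_zero_phase_impulse_response_is_symmetric():
    x = np.zeros(int(8 * RATE))
    k = len(x) // 2
    x[k] = 1.0
    y = bandpass_array(x, FilterSpec(0.3, 35.0), RATE)
    assert abs(int(np.argmax(np.abs(y))) - k) <= 1
    w = int(0.2 * RATE)
    seg = y[k - w : k + w + 1]
    assert np.allclose(seg, seg[::-1], atol=1e-5)


def test_filtering_idempotent_in_passband():
    t = np.arange(int(20 * RATE)) / RATE
    x = np.sin(2 * np.pi * 10.0 * t)
    once = bandpass_array(x, FilterSpec(0.3, 35.0), RATE)
    twice = bandpass_array(once, FilterSpec(0.3, 35.0), RATE)
    mid = slice(int(5 * RATE), int(15 * RATE))
    assert np.abs(twice[mid] - once[mid]).max() < 0.02


def test_band_edge_at_nyquist_rejected(rng):
    rec = _rec({"C3": rng.standard_normal(1000)})
    with pytest.raises(ValueError, match="Nyquist"):
        bandpass(rec, FilterSpec(0.3, 125.0))
    with pytest.raises(ValueError):
        FilterSpec(10.0, 5.0)


# --- artifact detection -----------------------------------------------------

def test_clean_background_yields_empty_mask(rng):
    rec = _rec({"C3": 40 * np.tanh(rng.standard_normal(5000))})  # bounded ±40
    assert detect_artifacts(rec).masked_seconds() == 0.0


def test_eeg_excursion_masks_plus_minus_three_seconds(rng):
    n = int(200 * RATE)
    x = 5 * rng.standard_normal(n)
    x[int(100 * RATE) : int(100.2 * RATE)] = 400.0
    rec = _rec({"C3": x})
    iv = detect_artifacts(rec).global_intervals
    assert iv.shape[0] == 1
    assert iv[0][0] == pytest.approx(97.0, abs=0.05)
    assert iv[0][1] == pytest.approx(103.2, abs=0.05)


def test_nearby_excursions_merge_into_one_interval(rng):
    n = int(200 * RATE)
    x = np.zeros(n)
    x[int(100 * RATE) : int(100.2 * RATE)] = 400.0
    x[int(104 * RATE) : int(104.2 * RATE)] = 400.0
    iv = detect_artifacts(_rec({"C3": x})).global_intervals
    assert iv.shape[0] == 1
    assert iv[0][0] == pytest.approx(97.0, abs=0.05)
    assert iv[0][1] == pytest.approx(107.2, abs=0.05)


def test_emg_threshold_is_fifty_microvolts(rng):
    n = int(60 * RATE)
    burst = np.zeros(n)
    burst[int(30 * RATE) : int(31 * RATE)] = 100.0 * rng.standard_normal(int(RATE))
    rec = _rec({"C3": np.zeros(n), "EMG": burst}, kinds={"EMG": "EMG"})
    iv = detect_artifacts(rec).global_intervals
    assert iv.shape[0] == 1
    assert iv[0][0] == pytest.approx(27.0, abs=0.1)
    # the same burst on an EEG channel stays under the ±300 µV EEG rule
    rec2 = _rec({"C3": burst})
    assert detect_artifacts(rec2).masked_seconds() == 0.0


def test_masked_duration_monotone_in_artifact_count():
    h = Hypnogram(["N2"] * 20)
    rec, _ = generate_recording(h, seed=0)
    masked = []
    for rate_per_hour in (0.0, 12.0, 40.0):
        noisy, _ = inject_artifacts(rec, rate_per_hour, seed=3)
        masked.append(detect_artifacts(noisy).masked_seconds())
    assert masked[0] <= masked[1] <= masked[2]
    assert masked[2] > masked[0]


def test_injected_artifact_time_recovered():
    h = Hypnogram(["N2"] * 40)
    rec, _ = generate_recording(h, seed=1)
    noisy, injected = inject_artifacts(rec, 20.0, seed=2)
    mask = detect_artifacts(noisy).global_intervals
    covered = 0.0
    for a, b in injected:
        for u, v in mask:
            lo, hi = max(a, u), min(b, v)
            covered += max(0.0, hi - lo)
    total = float((injected[:, 1] - injected[:, 0]).sum())
    assert covered / total >= 0.99


def test_epoch_resolved_mask_rounds_to_epochs(rng):
    n = int(200 * RATE)
    x = np.zeros(n)
    x[int(100 * RATE) : int(100.2 * RATE)] = 400.0
    cfg = ArtifactConfig(epoch_resolved=True)
    iv = detect_artifacts(_rec({"C3": x}), cfg).global_intervals
    assert iv[0][0] % 30.0 == 0.0
    assert iv[0][1] % 30.0 == 0.0
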