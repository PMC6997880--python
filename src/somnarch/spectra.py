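"""Power spectral density of artifact-free sleep and band-power extraction.

The estimator follows the Welch convention used in sleep labs: 5-s Hanning
windows advancing by 1 s (4-s overlap), restricted to windows that lie
wholly inside a contiguous run of eligible 30-s epochs and that do not
touch the artifact mask.  Averaged squared FFT magnitudes are normalised
by the effective noise bandwidth so that unit-variance white noise
integrates to 1 over [0, Nyquist]:

    density[k] = 2 * |X_k|^2 / (rate * sum(w^2))      (one-sided; DC and
                                                       Nyquist unscaled)

which equals dividing the window-gain-corrected power by ``rate * ENBW``
with ``ENBW = N * sum(w^2) / sum(w)^2`` bins.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import ArtifactMask, Hypnogram, Recording

__all__ = ["PSDResult", "NoDataError", "welch_psd", "band_power", "compare_spectra"]

WINDOW_S = 5.0
HOP_S = 1.0
DEFAULT_FMIN = 0.6
DEFAULT_FMAX = 20.0


class NoDataError(RuntimeError):
    """Raised when no artifact-free window exists for the requested stages."""


@dataclass
class PSDResult:
    """Channel x frequency power density grid (µV²/Hz) at 0.2 Hz spacing."""

    freqs: np.ndarray
    power: np.ndarray  # (n_channels, n_freqs)
    channels: list[str]
    n_windows: int
    stages_used: frozenset[str]

    def channel(self, label: str) -> np.ndarray:
        return self.power[self.channels.index(label)]


def _eligible_window_starts(
    h: Hypnogram, mask: ArtifactMask, stages, duration: float
) -> np.ndarray:
    """Start times of 5-s windows inside contiguous eligible-epoch runs."""
    want = set(stages)
    starts: list[float] = []
    run_start = None
    bounds: list[tuple[float, float]] = []
    for i, s in enumerate(h.stages):
        if s in want and run_start is None:
            run_start = i * h.epoch_s
        elif s not in want and run_start is not None:
            bounds.append((run_start, i * h.epoch_s))
            run_start = None
    if run_start is not None:
        bounds.append((run_start, h.n_epochs * h.epoch_s))
    for a, b in bounds:
        b = min(b, duration)
        t = a
        while t + WINDOW_S <= b + 1e-9:
            if not mask.overlaps(t, t + WINDOW_S):
                starts.append(t)
            t += HOP_S
    return np.asarray(starts)


def welch_psd(
    rec: Recording,
    mask: ArtifactMask | None = None,
    h: Hypnogram | None = None,
    stages=("N2", "SWS"),
    channels: list[str] | None = None,
    fmin: float = DEFAULT_FMIN,
    fmax: float = DEFAULT_FMAX,
) -> PSDResult:
    """Welch PSD over artifact-free epochs of the requested stages.

    With ``h=None`` the whole recording is treated as one eligible run.
    Raises :class:`NoDataError` when zero eligible windows remain.
    """
    mask = mask or ArtifactMask.empty()
    if h is None:
        n_ep = int(rec.duration // 30.0) or 1
        h = Hypnogram(["N2"] * n_ep, epoch_s=rec.duration / n_ep)
        stages = ("N2",)
    channels = channels or rec.labels_of_kind("EEG")
    starts = _eligible_window_starts(h, mask, stages, rec.duration)
    if starts.size == 0:
        raise NoDataError(
            f"no artifact-free {WINDOW_S:g}-s window in stages {sorted(set(stages))}"
        )
    nper = int(round(WINDOW_S * rec.rate))
    w = np.hanning(nper)
    scale = 1.0 / (rec.rate * (w**2).sum())
    freqs = np.fft.rfftfreq(nper, d=1.0 / rec.rate)
    idx = np.round(starts * rec.rate).astype(int)
    idx = idx[idx + nper <= rec.n_samples]
    if idx.size == 0:
        raise NoDataError("eligible windows fall outside the recording")

    rows = []
    for label in channels:
        x = rec.get(label)
        segs = np.stack([x[i : i + nper] for i in idx])
        spec = np.fft.rfft(segs * w, axis=-1)
        p = (spec.real**2 + spec.imag**2).mean(axis=0) * scale
        p[1:-1] *= 2.0  # one-sided: fold negative frequencies
        rows.append(p)
    power = np.vstack(rows)
    keep = (freqs >= fmin - 1e-9) & (freqs <= fmax + 1e-9)
    return PSDResult(
        freqs=freqs[keep],
        power=power[:, keep],
        channels=list(channels),
        n_windows=int(idx.size),
        stages_used=frozenset(stages),
    )


def band_power(psd: PSDResult, lo_hz: float, hi_hz: float) -> np.ndarray:
    """Per-channel band power: sum of density * 0.2 Hz over lo <= f <= hi."""
    sel = (psd.freqs >= lo_hz - 1e-6) & (psd.freqs <= hi_hz + 1e-6)
    if not sel.any():
        raise ValueError(f"no PSD bins inside [{lo_hz}, {hi_hz}] Hz")
    df = float(np.median(np.diff(psd.freqs)))
    return psd.power[:, sel].sum(axis=1) * df


def compare_spectra(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Per-bin bootstrapped two-sample t test between subject spectra.

    ``group_a``/``group_b`` are (n_subjects, n_freqs) arrays (one value per
    subject per bin, e.g. subject-mean PSD for one channel).  Subjects are
    resampled with replacement under the pooled-mean null; the two-tailed p
    per bin is the add-one-smoothed fraction of bootstrap |t| exceeding the
    observed |t|.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need >= 2 subjects per group")
    if a.shape[1] != b.shape[1]:
        raise ValueError("frequency grids differ between groups")
    low_boot = n_boot < 100

    def tstat(x, y):
        nx, ny = x.shape[0], y.shape[0]
        vx = x.var(axis=0, ddof=1)
        vy = y.var(axis=0, ddof=1)
        sp = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        denom = np.sqrt(sp * (1.0 / nx + 1.0 / ny))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (x.mean(axis=0) - y.mean(axis=0)) / denom
        return np.where(denom > 0, t, 0.0)

    t_obs = tstat(a, b)
    # centre both groups on the pooled mean so resamples satisfy H0
    pooled = np.vstack([a, b]).mean(axis=0)
    a0 = a - a.mean(axis=0) + pooled
    b0 = b - b.mean(axis=0) + pooled
    rng = np.random.default_rng(seed)
    exceed = np.zeros(a.shape[1])
    for _ in range(n_boot):
        ia = rng.integers(0, a.shape[0], a.shape[0])
        ib = rng.integers(0, b.shape[0], b.shape[0])
        tb = tstat(a0[ia], b0[ib])
        exceed += np.abs(tb) >= np.abs(t_obs)
    p = (exceed + 1.0) / (n_boot + 1.0)
    return {"t": t_obs, "p": p, "n_boot": n_boot, "low_boot": low_boot}
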