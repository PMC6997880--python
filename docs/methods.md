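# Methods

This note documents the models, detector conventions and numerical choices
behind `somnarch`, in enough detail to reproduce or criticise them.

## Signal model and conventions

All signals are uniformly sampled potentials in µV; time is seconds from
recording start, intervals are half-open `[start, end)`, and 30-s scoring
epochs are 0-indexed. Sleep stages use the vocabulary `W, N1, N2, SWS, REM,
UNSCORED` (`N3` accepted as an input alias for SWS). Analyses assume a
linked-mastoid reference; raw recordings carrying M1/M2 are re-referenced by
subtracting `mean(M1, M2)` from every EEG channel.

Acquisition-style filtering is a 4th-order Butterworth applied
forward–backward (zero phase, effective 8th order): EEG/EOG 0.3–35 Hz, EMG
10–100 Hz. Zero-phase filtering matters because event trough times feed the
coupling delays downstream; the impulse response is symmetric to ~1e-5
relative amplitude and group delay is below one sample.

## Artifact masking

A sample is an artifact seed when the 10–80 Hz EMG leaves ±50 µV or the
0.3–33 Hz EEG leaves ±300 µV. Every seed poisons ±3 s; per-channel
intervals are merged and unioned across channels, and all downstream
analyses intersect their windows with the clean complement. The mask is
sample-resolved by default; a whole-epoch variant
(`ArtifactConfig(epoch_resolved=True)`) rounds intervals to 30-s epochs. A
human-override mask can be merged in (`run_night(extra_mask=...)`).

## Power spectral density

Welch estimation on 5-s Hanning windows advancing by 1 s (4-s overlap).
Windows must lie wholly inside one contiguous run of eligible-stage epochs
and must not touch the artifact mask — no stitching across gaps, which
would leak discontinuity energy. Normalisation:

    density[k] = 2 |X_k|^2 / (rate * sum(w^2)),

one-sided with DC and Nyquist unscaled — i.e. division by `rate * ENBW`
with `ENBW = N sum(w^2)/sum(w)^2` bins. This convention is fixed by two
oracles in the test suite: unit-variance white noise integrates to 1.0 over
[0, Nyquist] (±5%), and a pure sine of amplitude A carries A²/2 band power
(±2%). The grid spacing is exactly 0.2 Hz (5-s windows); the reporting
range defaults to 0.6–20 Hz. Band powers are sums of density × 0.2 Hz over
bins with `lo ≤ f ≤ hi` (a 1e-6 Hz tolerance absorbs float grid error);
slow-wave activity (SWA) uses 2–3.2 Hz.

Group spectra are compared per frequency bin with a bootstrapped two-sample
t test: groups are centred on the pooled mean (null), subjects resampled
with replacement `n_boot` times, and the two-tailed p per bin is the
add-one-smoothed fraction of bootstrap |t| at or above the observed |t|.

## Event detectors

Detection statistics (spindle SD, SO candidate means, 3-SD pruning) are
computed per night and per channel over artifact-free samples of the
eligible stages (`DetectorConfig.stages`, default N2+SWS; spindle/SO
analyses of the cohort experiments use N2 only, since spindle and SO
microarchitecture is an N2 analysis and slow-wave-rich SWS would inflate
the spindle threshold for subjects who have SWS). Events straddling an
epoch boundary belong to the epoch containing their trough.

### Spindles

Per channel: band-pass to 9–12 Hz (slow) or 12–15 Hz (fast, 4th-order
zero-phase Butterworth), form the 0.2-s moving-RMS envelope, and threshold
at 1.5 × SD of the band-filtered signal — a single, deliberately low
threshold. Supra-threshold runs closer than 0.25 s are merged; runs of
0.5–3.0 s become events. Recorded per event: peak-to-peak amplitude of the
filtered signal, duration, core frequency, trough time, and the envelope
maximum (`peak_time`), which is the event anchor used for coupling. Core
frequency is the median inter-zero-crossing half-period of the filtered
segment — robust to the noise-dominated run edges (a plain crossing count
over the run underestimates by several tenths of a Hz).

Two guards keep the slow/fast classes exclusive, because a Hanning-tapered
burst just across the 12 Hz border leaks transient energy into the
neighbouring band that can cross the low threshold: an event is dropped
when its measured core frequency falls outside the detection band (a
band-passed tone keeps its own frequency, so genuine leakage is caught),
and a detection is attributed to the band whose envelope dominates at the
anchor. Both are config switches (`spindle_require_core_in_band`,
`spindle_band_attribution`, default on).

Density is events per artifact-free N2 minute (configurable through the
`EventList.denominator_min` field).

### Slow oscillations

Candidates are full cycles in the cycle grammar
positive-to-negative zero crossing → negative half-wave (trough) →
negative-to-positive crossing → positive half-wave (peak) →
positive-to-negative crossing, with total duration 0.9–2.0 s — which is
precisely the 0.5–1.11 Hz target range expressed as durations. The signal
is filtered with a broad slow band, 0.16–4 Hz order-2 zero-phase
Butterworth, *not* with a 0.5–1.11 Hz band-pass: filtering a single cycle
at its own spectral width rings and splits one oscillation into several
candidates, and a steep high-pass drags the trough ~10 ms toward the cycle
centre; the broad filter keeps the trough faithful to ~2 ms. Crossing
times are linearly interpolated.

A candidate is retained when its trough-to-peak amplitude **and** its
negative-peak magnitude both reach 1.25 × the respective means over that
channel's candidates — a relative criterion, so a population of identical
candidates retains nothing, and mixing populations of amplitude a and 3a
(mean 2a, cut 2.5a) retains exactly the 3a population. Slope is
|trough| / (time from trough to the next negative-to-positive crossing).
The event `offset` is the terminal positive-to-negative crossing (end of
the up-state); the coupling window builds on it.

### AASM-tailored slow waves and estimated SWS

Slow waves use the same cycle grammar on the four scoring derivations
(F3, F4, C3, C4 against linked mastoids) with durations 0.5–2.0 s
(0.5–2 Hz) and an absolute trough-to-peak amplitude window of 75–400 µV.
The filter is 0.16–8 Hz (order 2); the slightly wider top sharpens
zero-crossing localisation so per-epoch duration sums are accurate (a 1-s
wave measures 1.02 s instead of 1.06 s under the 4-Hz top). Amplitude is
read from the *broadband* signal at the band-located extrema so the
absolute bounds are not biased by filter attenuation, with a 0.5 µV
allowance on the bounds because the sampled extremum of a wave sitting
exactly on a bound falls a fraction of a microvolt short of its continuous
value. The cost of broadband measurement is extra noise sensitivity — in
realistic background the detector over-counts relative to an
injected-event ledger (the surplus includes genuine slow oscillations,
which meet the AASM definition, plus background excursions); the estimated
SWS classifier below is robust to this because per-epoch *summed durations*
of background detections stay far below the 6-s rule.

Per derivation, detections whose duration, frequency or amplitude deviates
more than 3 SD from that channel's mean are pruned (switchable). Detection
runs per derivation and the per-epoch summed durations are averaged across
the four derivations (not detection on an averaged signal — the 3-SD rule
is per channel). An N2/SWS epoch whose averaged summed duration strictly
exceeds 6 s (20% of 30 s) is classified as estimating SWS; 6.0 s exactly is
not. Reported per night: estimated SWS minutes and slow-wave density per
artifact-free NREM minute (per derivation).

## SO–spindle coupling

A fast spindle is nested in a slow oscillation when its anchor (envelope
maximum; onset-anchoring available) lies in
`[trough_time, offset + 0.5 s]` — from the down-state trough to half a
second past the terminal positive-to-negative zero crossing. Each spindle
counts once, for the earliest SO whose window contains it, per channel.
Delay = anchor − trough; the per-channel summary reports the coupled
count, mean delay, delay SD ("delay dispersion"), and mean amplitude and
duration of the coupled SOs and spindles. Delays are measured to the
trough, the unambiguous anchor of the down-state.

`event_locked_average` averages band-filtered segments aligned on event
troughs (trough at t = 0), dropping and counting events whose window
crosses a recording edge.

## Hypnogram metrics

Between lights-off and lights-on: TST = minutes in any sleep stage; sleep
efficiency = 100 × TST / time in bed; sleep onset = first epoch of any
sleep stage (AASM convention; a persistent-sleep rule is a flag); REM
latency = onset → first REM epoch; WASO = wake minutes after onset.
Stability: awakening index = sleep→W epoch transitions per TST hour;
transitions/h = any stage change per hour in bed; wake–sleep transitions
per TST minute; NREM/REM stability = mean duration of maximal same-
superstage runs (NREM = {N1, N2, SWS}). The arousal index consumes an
annotation table (onset_s, duration_s) and counts arousals whose onset
falls in a sleep epoch, per TST hour.

Two constructs originate in methodological literature whose exact rules are
not restated in our sources, so the defaults here are reasonable readings
and explicitly non-authoritative, implemented as replaceable functions:
a *functional-uncertainty period* is a maximal run in which every
consecutive epoch pair changes stage, with at least two consecutive changes
(≥3 epochs of continuous instability); TFU is the minutes covered by such
runs and the reported ratio is TFU/TST.

## Statistics

* **Mann-Whitney U**: U = min(U1, U2) from midrank sums. Asymptotic p uses
  z = (U − n1n2/2)/√(n1n2(N+1)/12) with tie-corrected variance and *no*
  continuity correction (matching common clinical-software output, e.g.
  U = 3 at n = 4 vs 10 → p = 0.016). Exact p enumerates all C(N, n1)
  assignments of the pooled midranks and counts those whose min-tail U is
  at or below the observed one (U = 3 → 14/1001 = 0.014); enumeration is
  used up to 10^6 combinations. Both values are always reported.
* **Effect size**: z from the same normal approximation, r = z/√N,
  d = 2r/√(1−r²). The formula is pinned by a test reproducing eleven
  published U → d pairs at (4, 10) within ±0.01.
* **t-based CI**: mean ± t_{n−1,0.975} · sd/√n.
* **Bootstrap difference**: resample each group with replacement (default
  1000 iterations), percentile 95% CI of the mean difference, two-tailed p
  with add-one smoothing ((count+1)/(n_boot+1)) so p is never zero.
  Percentile bootstrap CIs undercover somewhat below n ≈ 10 per group;
  that is a property of the method, not of this implementation.
* **ICC**: two-way model, absolute agreement, single measures (ICC(A,1))
  from the ANOVA mean squares; NaN for constant tables. Matches the
  pingouin implementation to 1e-6 in tests.
* **Friedman**: midrank chi-square with df = k − 1 (SciPy backend).

## Synthetic nights

The generator is first-class, tested code; it defines the conditions every
recovery experiment runs under.

* **Hypnogram**: first-order Markov chain whose transition rows are
  `s·e_i + (1−s)·π` with stickiness s (default 0.85; cohort experiments use
  0.7 for shorter bouts in short nights), so the stationary distribution
  equals the requested stage mix exactly while bouts last ~1/(1−s) epochs.
* **Background**: 1/f^α Gaussian noise (α = 1) with stage-dependent
  broadband RMS — defaults W 15, N1 18, N2 20, SWS 30, REM 18 µV — plus a
  white 8 µV RMS EMG channel. These are plausible scalp-EEG magnitudes for
  older adults; they are not fitted to any dataset.
* **Events**: spindles are sinusoids at a core frequency drawn uniformly
  from the band (slow 9.5–11.5, fast 12.5–14.5 Hz) under a Hanning
  envelope, duration U(0.5, 2.0) s, peak-to-peak amplitude from a truncated
  normal (slow 40±10, fast 50±10 µV). Slow oscillations and slow waves are
  single cycles (negative then positive half-wave), SO duration
  U(0.9, 2.0) s and trough-to-peak 140±30 µV, slow waves U(0.8, 1.6) s and
  150±50 µV truncated to 75–400. Default densities per eligible-stage
  minute: fast spindles 2.5 and slow 1.5 in N2; SO 1.5 (N2) / 5 (SWS);
  slow waves 2 (N2) / 14 (SWS) — the SWS rate is what makes a SWS epoch
  carry > 6 s of slow waves, consistent with the visual scoring rule.
  Densities are exact by construction (`round(density × stage minutes)`
  events are placed or the generator raises), same-kind events keep a 1-s
  gap, and all injections land identically on every EEG channel (scalp
  slow oscillations and spindles are near-global) with independent
  background per channel.
* **Ledger**: every injection is logged per channel. Spindle onsets/offsets
  are logged at the ≥10%-of-envelope support; the outer taper tails sit
  below any realistic noise floor and no detector (or scorer) can see
  them, so scoring detection onsets against them would only measure the
  taper, not the detector.
* **Coupling scenarios**: a requested fraction of fast spindles is placed
  with the envelope peak at a fixed lag after an injected SO trough.
* **Artifacts**: EMG noise bursts (RMS 150 µV) and slow ±500 µV EEG bumps
  of 0.5–2 s at a requested hourly rate, with logged intervals.

What the generator does **not** emulate: topographic gradients across
channels, sleep-cycle ultradian structure, spindle chirp, SO–spindle phase
dynamics beyond a fixed lag, K-complexes, EOG/ECG physiology, and real
scorer noise in hypnograms. Passing recovery tests therefore demonstrates
correctness of the implementations under the stated signal model — not
clinical performance on real polysomnography.

## Cohort experiments

`simulate_cohort` renders a patient-like group (n = 4) against controls
(n = 10), one night per subject (default 20 min at 250 Hz). The
patient-like condition scales slow-wave density by ×0.1 *and* uses a stage
mix with essentially no scored SWS — visual staging cannot call SWS
without slow waves occupying ≥20% of the epoch, so suppressed slow-wave
production implies near-zero scored SWS. Spindle and SO parameters are
identical across groups. Nights without N2 report spindle/SO variables as
missing. The headline experiment (50 replicates) checks that estimated SWS
minutes separate the groups (exact MWU p < 0.05) in ≥90% of replicates
while both spindle densities stay non-significant in ≥80%.

## Problem sizes and runtime

Recovery tests use 15–40-epoch single-stage nights at 250 Hz; the full
suite runs in ~3 minutes on one CPU and `scripts/acceptance.py` in
seconds. Simulations scale linearly in night length and channel count if
larger experiments are wanted.

## Known limitations

* The slow-wave detector's broadband amplitude read-out over-counts in
  high-amplitude backgrounds (see above); per-epoch summed durations and
  the 6-s rule absorb this, individual event counts do not.
* The 1.5-SD spindle threshold is intentionally low; on event-free signal
  it flags the tail of the background distribution (≈0.3/min under the
  default background). This mirrors the threshold's behaviour, not a bug.
* Exact MWU enumeration is O(C(N, n1)); beyond 10^6 combinations only the
  asymptotic p is returned.
* The functional-uncertainty and stability definitions are plausible
  defaults, not reproductions of their source formulations.
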