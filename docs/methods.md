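# Methods

This note documents the models, estimators and numerical choices behind
`dyadcoh`, in the order data flows through the pipeline.

## Synthetic dyad model

The generator emulates two seated partners mirroring continuous forearm
oscillations while improvising speed and amplitude, with EEG that linearly
tracks their synchronization error.

**Movement.** Each participant is a phase oscillator. The instantaneous
frequency performs a mean-reverting (AR(1)/Ornstein–Uhlenbeck) walk around
`base_freq` (default 1.0 Hz) with stationary SD `drift_std` (default 0.2 Hz)
and relaxation time 10 s; a floor of 0.1 Hz prevents non-physical
frequencies. A mean-reverting walk was preferred to a free random walk so
that 180 s trials stay in a plausible movement band. Coupling is a delayed
phase attraction integrated by explicit Euler at the motion rate:

    dφ_B/dt = ω_B(t) + g · sin(φ_A(t − d) − φ_B(t))

with `d = follower_delay_s` (default 0.2 s) and gain
`g = coupling_strength · 2π · 1.0 s⁻¹`. In the `follower` condition B
follows A, in `leader` the roles swap, in `joint` both couple at half gain.
At full coupling and zero drift the follower settles exactly at the
leader's phase delayed by `d` (a stable fixed point of the update), which
the test suite verifies against an independently coded integrator.
Displacement is `amp(t)·sin(φ(t))` along an axis tilted ~10° off
horizontal (per-trial draw, emulating seating geometry), with amplitude
following its own mean-reverting walk (relative SD `amp_drift_std` = 0.15)
and 1% white positional noise (`noise_rel`). Setting `drift_std`,
`amp_drift_std` and `noise_rel` to zero gives the deterministic
pure-sinusoid limit used by closed-form tests.

**Error signal.** The derived error `|x_A − x_B|` of two near-synchronous
~1 Hz oscillations concentrates its power at the rectification harmonics
(2·f and above, decaying fast) plus slow drift-driven components — >90% of
its variance lies below 6 Hz for `base_freq ≤ 1.5` Hz, which is the regime
the downstream 0–6 Hz band targets.

**EEG.** `n_channels` channels of unit-variance Gaussian background with a
1/f^a spectrum (a = `background_exponent` = 1, flattened below 0.1 Hz to
bound drifts). The first `n_tracking_channels` additionally carry the error
signal circularly shifted by `tracking_lag_s` (positive = EEG lags error;
the wraparound of ≤ 500 samples in ≥ 20 k is negligible and keeps shifts
sample-exact), scaled so tracking-power / background-power =
`tracking_snr`. `tracking_band_hz` (default `None`) optionally low-passes
the embedded tracking component (4th-order zero-phase Butterworth),
modelling band-limited neural tracking; without it the embedded component
is broadband and coherent at *all* frequencies, which is the correct
noiseless-limit contract but not the band-confined physiology. All draws
come from per-component substreams of the single trial seed, so trials are
bit-reproducible.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: biomechanics (no force dynamics, no HKB-style
bistability), eye or muscle artifacts, volume conduction between channels,
inter-subject variability of spectra, and any nonlinear or
frequency-specific neural coding of error. The generator guarantees only
that the *statistical structure the estimators assume* (drifting
near-sinusoidal coordination with asymmetric lagged coupling; a noisy,
time-shifted linear image of a sub-6 Hz error in some channels) is present
with known parameters.

## Error construction

The principal movement axis is fitted by PCA **on the concatenated
two-participant data of a trial** and both traces are projected onto that
single axis, centered by the joint mean. A per-participant PCA is available
(`principal_axis_project` per trace) but is not the default: the difference
of projections onto two different axes is not a spatial distance, and
joint centering lets a constant positional offset between partners survive
into the error. The axis sign is fixed by requiring a nonnegative loading
on the nominal horizontal axis.

Projections are resampled 240 → 500 Hz *before* the absolute difference is
taken (resampling the rectified signal would alias its kinks). Polyphase
resampling uses a Kaiser window with β = 20: passband ripple < 1e-9, so a
constant offset between partners is preserved to ~1e-6 relative accuracy.

## Instantaneous-frequency control

`f_inst` is the unwrapped Hilbert-phase derivative (central differences,
×fs/2π). Before the second derivative, `f_inst` is zero-phase low-passed at
0.5 Hz (configurable): the discrete analytic signal of a ~1 Hz movement
carries deterministic ripple near twice the carrier whose derivative would
otherwise swamp the slow frequency adjustments this control indexes —
instantaneous frequency is only meaningful on timescales longer than a
cycle. The rectified derivative's first/last second is tapered by a
raised-cosine ramp against Hilbert edge artifacts. On a linear chirp the
recovered |df/dt| matches the generating slope to <1%; on sinusoidal FM it
matches the phase-law derivative to <5% RMS.

## Preprocessing

All filters are zero-phase, because the lag scan interprets time lags and
must not inherit group delay. The 0.1 Hz high-pass is realized as
*subtraction of a drift estimate*: the signal is polyphase-decimated ~50×,
low-passed with a 4th-order Butterworth at the corner (normalized cutoff
~0.04, well conditioned), interpolated back and subtracted. Direct
forward-backward IIR filtering at a normalized cutoff of 4e-4 measurably
injects low-frequency wander (~0.1 of a unit tone's amplitude) from
coefficient round-off; the subtraction form has the same magnitude target
(verified: DC removed to 1e-8 relative, 2 Hz passband within ±0.5 dB) and
exactly zero phase. Mains notches (Q = 30 IIR, applied forward-backward)
are placed at 50·{1..k} Hz below Nyquist. Decimation (2048 → 500 Hz) is
polyphase. Average reference subtracts the per-sample channel mean.

## Spectral estimation

Epochs are 5 s with 50% overlap, trailing partials dropped (180 s → 71
epochs); each epoch is demeaned. The taper family is DPSS with exactly
K = 3 tapers, i.e. NW = (K+1)/2 = 2 and a realized half-bandwidth of
(K+1)/(2T) = **0.4 Hz** for T = 5 s — with K = 3 enforced, a nominal
±0.3 Hz is not attainable at this epoch length, and the implementation
reports the realized value rather than guessing at padding. A single
Hanning taper is available via `taper="hann"`. Coefficients are scaled so
products are one-sided spectral densities (Parseval-exact against the
tapered time series).

Condition-level coherence is the **coherence of the pooled CSD** (auto- and
cross-spectra averaged over all epochs × tapers × trials, then
normalized), not the mean of per-trial coherences — pooling first is the
lower-variance estimator and makes the surrogate comparison exact.
Undefined cells (zero auto-power) propagate as NaN, never as zero, and are
skipped by band averages. The 0–6 Hz band average includes the 6.0 Hz bin.
Calibration (reproduced by `scripts/acceptance.py`): for independent
Gaussian inputs pooled over N segment-tapers the mean magnitude coherence
matches the analytic E[coh] ≈ sqrt(π/(4N)) within ~1%, and for
channel = signal + independent noise the estimate converges to
sqrt(snr/(1+snr)).

The coherence/error-power ratio `coh(f)/S_yy(f)` quantifies tracking per
unit of error power (halving the error amplitude quarters `S_yy` and
quadruples the ratio at fixed coherence); a 0–6 Hz band-averaged variant
is provided.

## Surrogate baseline

Trial shuffling uses **derangements only** (9 for 4 trials, not all 4! =
24 permutations): identity pairings would leak genuine coherence into the
chance estimate. For every condition and derangement, each trial's EEG is
paired with the deranged trial's error using the identical pooled-CSD
settings; the resulting spectra are averaged over derangements and
conditions into one baseline per participant and channel. Cross-paired
trials of unequal length are truncated to the shorter member (with a
warning). Validity, verified by simulation: at `tracking_snr = 0` the
real-minus-surrogate band difference is centered on zero; at
`tracking_snr = 4` it is positive in ≥95% of simulated participants.

## Lag scan

Lags run from −2 to +2 s in 0.02 s steps (201 lags). Each lag is an exact
integer-sample shift at 500 Hz (0.02 s = 10 samples): EEG at time t is
compared with error at t − τ, so a positive peak lag means the brain
signal lags the error. Non-overlapping ends are truncated and the overlap
re-epoched; coherence is band-averaged over 0–6 Hz (the band that carries
the tracking) per lag. Peak ties break toward the smallest |lag|, negative
before positive. Group averaging means profiles across member channels
first, then re-extracts the peak from the averaged profile. Recovery
performance at `tracking_snr = 1` (60 s of data per participant): median
|recovered − true| = 0 over ground-truth lags {−0.2, 0, 0.1, 0.3} s, with
single-participant worst cases of a few grid steps.

## Cluster statistics

Point-wise statistics along the frequency axis (1-D adjacency; the
analysis operates on channel-averaged spectra): paired t for
real-vs-surrogate and condition contrasts, Pearson r (converted to t with
n−2 df) for coherence–error-magnitude relations. The cluster-defining
threshold is the two-sided parametric critical value at α = 0.05
(configurable). Cluster mass is Σ|t| over each maximal contiguous
supra-threshold run; zero-variance columns give ±∞ (supra-threshold by
construction), undefined correlations give NaN (sub-threshold). The null
is 1000 random sign flips of the per-subject differences (subject-label
shuffles of one variable for correlations, since sign flips are undefined
there); permutations without a supra-threshold cluster contribute maximum
mass 0. P-values use the add-one convention (b+1)/(m+1) — never exactly
zero, unbiased under exchangeability — with the raw proportion b/m behind
a flag. With `exact=True` all 2^n sign patterns are enumerated (n ≤ 20).
Calibration: familywise error 0.05 ± 0.02 under a 56-subject × 51-frequency
null (measured 0.035–0.07 across seeds at 200–400 datasets).

## Pipeline

Stages `simulate → analyze → stats` each read only the previous stage's
files in the run directory (a missing prerequisite aborts with a message
naming the stage to run); `summarize` tabulates a finished run. The single
global seed is fanned out per dyad/condition/trial through
`numpy.random.SeedSequence`, so reruns with the same config are
bit-identical (manifest records SHA-256 of every CSV/JSON output).
Intermediate arrays live in one HDF5 container per run; final tables are
CSV (long format: participant, condition, channel, frequency, coherence,
kind), and the cluster report is JSON.

## Problem sizes in the validation suite

The statistical test suite and `scripts/acceptance.py` run Monte-Carlo
studies at deliberately moderate sizes chosen to keep a full run on one
CPU in a few minutes: estimator calibration with 100–200 replications of
N = 60 segment-tapers; lag recovery with 20 (suite) or 8 (script)
participants per ground-truth lag at 60 s per participant; surrogate
validity with 100/40 participants of 4 × 45 s trials; cluster familywise
error with 400/200 datasets at 200 permutations; qualitative
follower/leader contrasts with 12/8 participants per group. Tolerances are
set from the estimators' sampling theory (e.g. two Monte-Carlo standard
errors), not from the realized draws. The band-confinement check sets the
generator's tracking low-pass corner to 4 Hz: with a 4th-order rolloff
plus the ±0.4 Hz multitaper smoothing this is what "tracking confined
below 6 Hz" requires — a corner *at* 6 Hz leaves coherent content near
7 Hz.

## Known limitations

- Sensor-space only: no source localization, head models or anatomical
  ROIs; channel groups stand in for regions of interest.
- No artifact correction (ICA, channel interpolation) — deliberately
  refused at the API level; real recordings need external cleaning first.
- The surrogate baseline assumes trials within a condition are
  exchangeable realizations; slow non-stationarities across trials would
  bias it.
- Magnitude coherence is phase-blind within a frequency bin; the lag
  scan's temporal resolution therefore comes from epoch-windowed
  misalignment and broadband structure, not from per-bin phase, and
  degrades for strongly narrowband error signals.
- The movement control is a single scalar signal; it cannot capture
  multivariate motor confounds.
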