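# dyadcoh

**EEG tracking of self-other movement synchronization error in dyadic
(hyperscanning) experiments.**

When two people synchronize improvised movements — e.g. mirrored forearm
oscillations in a "mirror game" — their brains continuously monitor how far
apart the two movements are. `dyadcoh` implements a complete sensor-space
analysis of this *neural error tracking* for paired motion-capture + EEG
recordings, together with a synthetic coupled-oscillator dyad generator with
known ground truth, so every estimator in the chain can be validated by
parameter recovery.

It is intended for researchers analyzing dyadic coordination experiments
(leader/follower/joint designs), and for methodologists who want a tested,
reproducible reference implementation of time-lagged coherence with
trial-shuffled baselines and cluster permutation statistics.

## The analysis

1. **Self-other error.** Both partners' positions are projected onto one
   common principal movement axis (PCA on the concatenated traces), the
   projections are polyphase-resampled from the motion-capture rate (240 Hz)
   to the EEG rate (500 Hz), and the error is the absolute difference
   `e(t) = |x_A(t) − x_B(t)|`.

2. **EEG-error coherence.** For each channel, magnitude coherence

   `Coh(f) = |S_xy(f)| / sqrt(S_xx(f) · S_yy(f))`

   is computed on 5 s epochs with 50% overlap (0.2 Hz resolution, 0–10 Hz),
   using DPSS multitapers (K = 3, realized half-bandwidth 0.4 Hz). Auto- and
   cross-spectral densities are pooled over all epochs, tapers and trials of
   a condition before the magnitude is taken.

3. **Surrogate baseline.** Chance coherence is estimated by pairing each
   trial's EEG with the error of a *different* trial: all 9 derangements of
   the 4 trials per condition, averaged over pairings and conditions.

4. **Lag scan.** Coherence (band-averaged 0–6 Hz) is recomputed for 201
   error time lags from −2 s to +2 s in 0.02 s steps; the peak lag estimates
   the latency of neural tracking (positive = brain lags error). An
   instantaneous-frequency movement control (|d f_inst/dt| from the Hilbert
   phase) runs through the same scan to rule out motor confounds.

5. **Cluster statistics.** Point-wise paired t (or correlation) statistics
   along the frequency axis are corrected by cluster-based permutation:
   contiguous supra-threshold runs, cluster mass = Σ|t|, null distribution of
   the maximum mass over sign-flip permutations.

## Worked example

```python
import dyadcoh as dc

cfg = dc.RunConfig(
    dyad=dc.DyadConfig(duration_s=45.0, n_channels=4, n_tracking_channels=2,
                       tracking_band_hz=4.0),
    n_dyads=2, n_trials=4, conditions=("follower", "leader", "joint"),
    tracking_snr_by_condition={"follower": 4.0, "leader": 1.0, "joint": 2.0},
    tracking_lag_by_condition={"follower": 0.3, "leader": 0.1, "joint": 0.2},
    lag_min=-1.0, lag_max=1.0, lag_step=0.02,
    n_perm=500, seed=1, out_dir="demo_run",
)
dc.run_pipeline(cfg)
print(dc.summarize("demo_run").round(3))
```

prints (abridged):

```
                    band_coherence  band_ratio  peak_coh[tracking]  peak_lag[tracking]
condition
follower                     0.315      84.140               0.603               0.290
joint                        0.313      95.448               0.570               0.205
leader                       0.268      49.203               0.462               0.100
surrogate_baseline           0.078         NaN                 NaN                 NaN
```

Reading it: tracking channels were configured to carry the error at
signal-to-noise 4/2/1 and latency 0.30/0.20/0.10 s in the three conditions.
The pipeline recovers exactly that ordering — band-averaged (0–6 Hz)
coherence well above the trial-shuffled baseline (0.078 ≈ chance for this
amount of pooling), and peak lags of 0.290/0.205/0.100 s. The accompanying
`clusters.json` reports one real-vs-surrogate cluster spanning 0–5 Hz
(mass 1419.9, p = 0.15 — with only 4 participants the 2⁴ sign-flip null
cannot reach p ≤ 0.05; run more dyads for inference). The same run is
available from the shell:

```bash
dyadcoh all --config cfg.yaml --seed 1 --out demo_run
dyadcoh summarize demo_run
```

## Layout

| module | contents |
|---|---|
| `dyadcoh.synthetic` | coupled-oscillator dyad + EEG generator (`DyadConfig`, `simulate_trial`) |
| `dyadcoh.kinematics` | principal-axis projection, error signal, instantaneous-frequency control |
| `dyadcoh.preprocess` | zero-phase high-pass/notch, decimation, average reference |
| `dyadcoh.spectral` | multitaper CSD, coherence, band averages, coherence/error-power ratio |
| `dyadcoh.surrogate` | derangement enumeration, trial-shuffled baseline |
| `dyadcoh.lagscan` | lag grid, lagged coherence, channel-group averaging, movement control |
| `dyadcoh.cluster` | point-wise t / correlation, cluster permutation correction |
| `dyadcoh.pipeline` / `dyadcoh.cli` | staged orchestration, manifests, `dyadcoh` CLI |

See `docs/methods.md` for the model, parameter and numerical details.
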