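"""Multitaper CSD, coherence, band averaging and the coherence/power ratio."""

import numpy as np
import pytest

import dyadcoh as dc
from dyadcoh.spectral import (
    csd_from_segments,
    half_bandwidth_hz,
    pool_spectra,
    tapered_segments,
)


class TestEpoch:
    def test_180s_at_500hz_gives_71_epochs(self):
        x = np.zeros(180 * 500)
        eps = dc.epoch(x, 500.0)
        assert eps.shape == (71, 2500)

    def test_exact_one_epoch(self):
        assert dc.epoch(np.zeros(2500), 500.0).shape[0] == 1

    def test_partial_trailing_window_dropped(self):
        # 7.4 s: second 5 s window (starting at 2.5 s) is incomplete
        assert dc.epoch(np.zeros(int(7.4 * 500)), 500.0).shape[0] == 1

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            dc.epoch(np.zeros(100), 500.0)

    def test_advance_is_half_epoch(self):
        x = np.arange(10 * 500, dtype=float)
        eps = dc.epoch(x, 500.0)
        assert eps[1, 0] == x[1250]


class TestMtCsd:
    def test_single_segment_is_rank_one(self, rng):
        """One epoch, one taper: |S_xy|^2 = S_xx * S_yy exactly."""
        x = rng.standard_normal((1, 1, 2500))
        y = rng.standard_normal((1, 2500))
        se = dc.mt_csd(x, y, 500.0, n_tapers=1, taper="hann")
        assert np.allclose(np.abs(se.S_xy) ** 2, se.S_xx * se.S_yy, rtol=1e-10)

    def test_parseval_on_pure_tone(self):
        """Total spectral power equals the tapered time-domain power."""
        fs = 500.0
        t = np.arange(2500) / fs
        x = np.sin(2 * np.pi * 1.0 * t)
        eps = x[None, None, :]
        se = dc.mt_csd(eps, x[None, :], fs, n_tapers=3, f_max=None)
        df = fs / 2500
        freq_power = np.sum(se.S_xx[0]) * df
        # time-domain reference: mean over tapers of sum((w*(x-mean))^2)
        from dyadcoh.spectral import _tapers
        taps = _tapers(2500, 3, "dpss")
        xd = x - x.mean()
        time_power = np.mean([np.sum((w * xd) ** 2) for w in taps])
        assert freq_power == pytest.approx(time_power, rel=1e-6)
        # and the 1 Hz bin dominates
        assert se.freqs[np.argmax(se.S_xx[0])] == pytest.approx(1.0)

    def test_frequency_grid_resolution(self):
        x = np.zeros((3, 2, 2500))
        y = np.zeros((3, 2500))
        se = dc.mt_csd(x + 1e-9, y + 1e-9, 500.0)
        assert np.allclose(np.diff(se.freqs), 0.2)
        assert se.freqs[0] == 0.0 and se.freqs[-1] == pytest.approx(10.0)

    def test_cauchy_schwarz_bound(self, rng):
        x = rng.standard_normal((8, 3, 2500))
        y = rng.standard_normal((8, 2500))
        se = dc.mt_csd(x, y, 500.0)
        assert np.all(np.abs(se.S_xy) ** 2 <= se.S_xx * se.S_yy * (1 + 1e-12))

    def test_mismatched_geometry_rejected(self, rng):
        with pytest.raises(ValueError):
            dc.mt_csd(rng.standard_normal((3, 1, 2500)),
                      rng.standard_normal((4, 2500)), 500.0)

    def test_realized_half_bandwidth(self):
        assert half_bandwidth_hz(3, 5.0) == pytest.approx(0.4)


class TestCoherence:
    def test_identity_gives_one(self, rng):
        x = rng.standard_normal(50 * 500)
        cs, _ = dc.pooled_coherence(x[None, :], x, 500.0)
        valid = np.isfinite(cs.coh[0])
        assert np.allclose(cs.coh[0][valid], 1.0, atol=1e-9)

    def test_independent_signals_match_analytic_null_mean(self, rng):
        """E[coh] ~ sqrt(pi/(4N)) for independent Gaussians (10 reps here;
        the deeper Monte-Carlo calibration lives in the acceptance suite)."""
        fs, n_ep = 500.0, 24
        n = int(n_ep * 5 * fs)
        vals = []
        for _ in range(10):
            X, freqs = tapered_segments(rng.standard_normal(n), fs, overlap=0.0)
            Y, _ = tapered_segments(rng.standard_normal(n), fs, overlap=0.0)
            vals.append(np.nanmean(dc.coherence(csd_from_segments(X, Y, freqs)).coh))
        expect = np.sqrt(np.pi / (4 * n_ep * 3))
        assert np.mean(vals) == pytest.approx(expect, rel=0.10)

    def test_snr_relation(self, rng):
        """channel = signal + noise at snr=1 -> coh ~ sqrt(0.5) +/- 0.05."""
        fs = 500.0
        n = int(100 * 5 * fs)
        x = rng.standard_normal(n)
        ch = x + rng.standard_normal(n)
        cs, _ = dc.pooled_coherence(ch[None, :], x, fs,
                                    epoch_len_s=5.0, overlap=0.0)
        assert np.nanmean(cs.coh) == pytest.approx(np.sqrt(0.5), abs=0.05)

    def test_scale_invariance(self, rng):
        x = rng.standard_normal((2, 30 * 500))
        y = np.abs(rng.standard_normal(30 * 500))
        c1, _ = dc.pooled_coherence(x, y, 500.0)
        c2, _ = dc.pooled_coherence(7.3 * x, y, 500.0)
        c3, _ = dc.pooled_coherence(x, 0.013 * y, 500.0)
        assert np.allclose(c1.coh, c2.coh, atol=1e-12, equal_nan=True)
        assert np.allclose(c1.coh, c3.coh, atol=1e-12, equal_nan=True)

    def test_strictly_below_one_for_pooled_noise(self, rng):
        x = rng.standard_normal((1, 30 * 500))
        y = np.abs(rng.standard_normal(30 * 500))
        cs, _ = dc.pooled_coherence(x, y, 500.0)
        valid = np.isfinite(cs.coh)
        assert np.all(cs.coh[valid] < 1.0)

    def test_monotone_in_tracking_snr(self):
        """Band coherence non-decreasing over snr {0, 0.25, 1, 4} at
        matched seeds."""
        fs = 500.0
        rng = np.random.default_rng(7)
        err = np.abs(rng.standard_normal(int(60 * fs)))
        prev = -1.0
        for snr in (0.0, 0.25, 1.0, 4.0):
            cfg = dc.DyadConfig(duration_s=60.0, tracking_snr=snr,
                                n_channels=1, n_tracking_channels=1, seed=99)
            eeg = dc.simulate_eeg(err, cfg)
            cs, _ = dc.pooled_coherence(eeg, err, fs)
            b = dc.band_average(cs)[0]
            assert b >= prev
            prev = b

    def test_zero_power_cells_are_nan_not_zero(self):
        fs = 500.0
        t = np.arange(int(30 * fs)) / fs
        y = np.sin(2 * np.pi * 1.0 * t) ** 2  # band-limited error-like signal
        x = np.vstack([np.zeros_like(t)])     # silent channel
        cs, _ = dc.pooled_coherence(x, y, fs)
        assert np.all(np.isnan(cs.coh))


class TestBandAverageAndRatio:
    def _flat_cs(self, coh_values):
        freqs = np.arange(0, 10.2, 0.2)
        coh = np.broadcast_to(np.asarray(coh_values)[:, None],
                              (len(coh_values), freqs.size)).copy()
        return dc.CoherenceSpectrum(freqs=freqs, coh=coh)

    def test_constant_spectrum(self):
        cs = self._flat_cs([0.42])
        assert dc.band_average(cs)[0] == pytest.approx(0.42)

    def test_linear_spectrum_gives_midpoint(self):
        freqs = np.arange(0, 10.2, 0.2)
        coh = (freqs / 20.0)[None, :]
        cs = dc.CoherenceSpectrum(freqs=freqs, coh=coh)
        out = dc.band_average(cs, 2.0, 4.0)
        assert out[0] == pytest.approx(3.0 / 20.0)

    def test_matches_direct_summation_oracle(self, rng):
        freqs = np.arange(0, 10.2, 0.2)
        coh = rng.uniform(size=(3, freqs.size))
        cs = dc.CoherenceSpectrum(freqs=freqs, coh=coh)
        mask = freqs <= 6.0 + 1e-9
        oracle = coh[:, mask].sum(axis=1) / mask.sum()
        assert np.allclose(dc.band_average(cs), oracle, atol=1e-14)

    def test_six_hz_bin_inclusive(self):
        freqs = np.arange(0, 10.2, 0.2)
        coh = np.zeros((1, freqs.size))
        coh[0, np.isclose(freqs, 6.0)] = 1.0
        cs = dc.CoherenceSpectrum(freqs=freqs, coh=coh)
        assert dc.band_average(cs)[0] > 0

    def test_nan_cells_excluded(self):
        freqs = np.arange(0, 10.2, 0.2)
        coh = np.full((1, freqs.size), 0.5)
        coh[0, 3] = np.nan
        cs = dc.CoherenceSpectrum(freqs=freqs, coh=coh)
        assert dc.band_average(cs)[0] == pytest.approx(0.5)

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError):
            dc.band_average(self._flat_cs([0.5]), 11.0, 12.0)

    def test_ratio_scaling_law(self, rng):
        """Quadrupling error power with unchanged coherence divides the
        ratio by 4."""
        freqs = np.arange(0, 10.2, 0.2)
        coh = rng.uniform(0.1, 0.9, size=(2, freqs.size))
        syy = rng.uniform(0.5, 2.0, size=freqs.size)
        mk = lambda s: dc.SpectralEstimate(
            freqs=freqs, S_xx=np.ones_like(coh), S_yy=s,
            S_xy=np.zeros_like(coh, dtype=complex), n_epochs=4, n_tapers=3)
        cs = dc.CoherenceSpectrum(freqs=freqs, coh=coh)
        r1 = dc.coherence_power_ratio(cs, mk(syy))
        r4 = dc.coherence_power_ratio(cs, mk(4 * syy))
        assert np.allclose(r4, r1 / 4.0)
        oracle = coh / syy[None, :]
        assert np.allclose(r1, oracle)

    def test_zero_coherence_gives_zero_ratio(self):
        freqs = np.arange(0, 10.2, 0.2)
        cs = dc.CoherenceSpectrum(freqs=freqs, coh=np.zeros((1, freqs.size)))
        se = dc.SpectralEstimate(freqs=freqs, S_xx=np.ones((1, freqs.size)),
                                 S_yy=np.ones(freqs.size),
                                 S_xy=np.zeros((1, freqs.size), dtype=complex),
                                 n_epochs=1, n_tapers=1)
        assert np.all(dc.coherence_power_ratio(cs, se) == 0)


def test_pool_spectra_weights_by_segments(rng):
    fs = 500.0
    X1, freqs = tapered_segments(rng.standard_normal(int(20 * fs)), fs)
    Y1, _ = tapered_segments(rng.standard_normal(int(20 * fs)), fs)
    X2, _ = tapered_segments(rng.standard_normal(int(50 * fs)), fs)
    Y2, _ = tapered_segments(rng.standard_normal(int(50 * fs)), fs)
    a = csd_from_segments(X1, Y1, freqs)
    b = csd_from_segments(X2, Y2, freqs)
    pooled = pool_spectra([a, b])
    joint = csd_from_segments(np.vstack([X1[:, None, :], X2[:, None, :]]),
                              np.vstack([Y1, Y2]), freqs)
    assert np.allclose(pooled.S_xy, joint.S_xy)
    assert np.allclose(pooled.S_xx, joint.S_xx)
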