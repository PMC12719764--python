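import numpy as np
import pytest

import dyadcoh as dc


@pytest.fixture
def fast_config():
    """A short, cheap trial configuration for unit tests."""
    def make(**kw):
        base = dict(duration_s=30.0, condition="joint", n_channels=2,
                    n_tracking_channels=1, seed=0)
        base.update(kw)
        return dc.DyadConfig(**base)
    return make


def simulate_participant(snr, seed, n_trials=4, duration_s=45.0, lag=0.1,
                         condition="joint", band=None, n_channels=2,
                         n_tracking=1):
    """One simulated participant: EEG and error series for n_trials trials."""
    eegs, errs = [], []
    for k in range(n_trials):
        cfg = dc.DyadConfig(duration_s=duration_s, condition=condition,
                            tracking_snr=snr, tracking_lag_s=lag,
                            tracking_band_hz=band, n_channels=n_channels,
                            n_tracking_channels=n_tracking,
                            seed=int(seed) * 16 + k)
        tr = dc.simulate_trial(cfg)
        pa, pb = dc.project_dyad(tr.pos_a, tr.pos_b)
        err = dc.compute_error(pa, pb, cfg.fs_motion, cfg.fs_eeg)
        eegs.append(tr.eeg_a)
        errs.append(err.values)
    return eegs, errs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
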