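"""Synthetic dyad generator.

Simulates two people performing mirrored, improvised forearm oscillations
(a "mirror game") together with multichannel EEG in which a subset of
channels linearly tracks the self-other synchronization error at a known
latency and signal-to-noise ratio.  Ground truth (coupling asymmetry,
follower delay, tracking lag, tracking SNR) is carried on every trial so
that downstream estimators can be validated by parameter recovery.

Model
-----
Each participant is a phase oscillator whose instantaneous frequency
performs a mean-reverting random walk around ``base_freq`` (the
"improvisation").  Coupling is a delayed phase attraction: the follower's
phase is pulled toward the leader's phase as it was ``follower_delay_s``
ago, with gain proportional to ``coupling_strength``.  In the ``joint``
condition both participants attract each other at half strength.
Positions are near-sinusoidal displacements along a slightly tilted
horizontal axis, with slowly drifting amplitude and a small amount of
white positional noise.

EEG channels are 1/f-shaped Gaussian background noise; the first
``n_tracking_channels`` additionally contain the error signal shifted by
``tracking_lag_s`` (positive lag = brain activity lags the error) and
scaled so that tracking-component power over background power equals
``tracking_snr``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = ["DyadConfig", "DyadTrial", "simulate_movement", "simulate_eeg", "simulate_trial"]

CONDITIONS = ("follower", "leader", "joint")

# rate constant (1/s) converting coupling_strength in [0, 1] into the
# relaxation rate of the follower's phase toward the leader's delayed phase
_COUPLING_GAIN_HZ = 1.0

# relaxation time of the frequency / amplitude mean-reverting walks
_DRIFT_TAU_S = 10.0

# instantaneous frequency never falls below this floor (Hz)
_FREQ_FLOOR_HZ = 0.1

# stream tags for per-component substreams derived from the single seed
_STREAM_FREQ_A, _STREAM_FREQ_B = 11, 12
_STREAM_AMP_A, _STREAM_AMP_B = 21, 22
_STREAM_NOISE_A, _STREAM_NOISE_B = 31, 32
_STREAM_TILT = 41
_STREAM_EEG = 51


@dataclass
class DyadConfig:
    """Ground-truth parameters of one simulated trial.

    Defaults follow the experimental regime the generator emulates:
    180 s trials, 240 Hz motion capture, 500 Hz EEG, near-1 Hz mirrored
    forearm oscillations in three leadership conditions.
    """

    duration_s: float = 180.0
    fs_motion: float = 240.0
    fs_eeg: float = 500.0
    condition: str = "joint"
    base_freq: float = 1.0
    drift_std: float = 0.2
    coupling_strength: float = 0.8
    follower_delay_s: float = 0.2
    tracking_lag_s: float = 0.1
    tracking_snr: float = 1.0
    n_channels: int = 8
    n_tracking_channels: int = 2
    seed: int = 0
    # amplitude drift (relative SD of the slow amplitude walk) and white
    # positional noise (relative to mean amplitude); zero both for the
    # deterministic pure-sinusoid limit
    amp_drift_std: float = 0.15
    noise_rel: float = 0.01
    # optional zero-phase low-pass (Hz) applied to the tracking component
    # embedded in EEG, modelling band-limited neural tracking; None embeds
    # the raw shifted error
    tracking_band_hz: float | None = None
    # exponent of the 1/f^a EEG background power spectrum
    background_exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fs_motion <= 0 or self.fs_eeg <= 0:
            raise ValueError("sampling rates must be positive")
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must lie in [0, 1]")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if abs(self.tracking_lag_s) >= self.duration_s:
            raise ValueError("tracking_lag_s exceeds trial duration")
        if abs(self.tracking_lag_s) > 1.0:
            # half of the +/-2 s lag-scan half-range: recovery would be
            # ambiguous near the scan edge
            raise ValueError("tracking_lag_s magnitude must be <= 1 s")
        if self.n_tracking_channels > self.n_channels:
            raise ValueError("n_tracking_channels cannot exceed n_channels")
        if self.drift_std < 0 or self.amp_drift_std < 0 or self.noise_rel < 0:
            raise ValueError("noise scales must be nonnegative")

    @property
    def n_motion(self) -> int:
        return int(round(self.duration_s * self.fs_motion))

    @property
    def n_eeg(self) -> int:
        return int(round(self.duration_s * self.fs_eeg))

    def replace(self, **kw) -> "DyadConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class DyadTrial:
    """One simulated trial: paired movement plus per-participant EEG."""

    pos_a: np.ndarray  # (n_motion, 2)
    pos_b: np.ndarray  # (n_motion, 2)
    eeg_a: np.ndarray  # (n_channels, n_eeg)
    eeg_b: np.ndarray  # (n_channels, n_eeg)
    condition: str
    ground_truth: DyadConfig

    def __post_init__(self) -> None:
        cfg = self.ground_truth
        for name, arr, n in (
            ("pos_a", self.pos_a, cfg.n_motion),
            ("pos_b", self.pos_b, cfg.n_motion),
        ):
            if abs(arr.shape[0] - n) > 1:
                raise ValueError(f"{name} length inconsistent with fs_motion")
        for name, arr in (("eeg_a", self.eeg_a), ("eeg_b", self.eeg_b)):
            if abs(arr.shape[1] - cfg.n_eeg) > 1:
                raise ValueError(f"{name} length inconsistent with fs_eeg")
        for name, arr in (
            ("pos_a", self.pos_a), ("pos_b", self.pos_b),
            ("eeg_a", self.eeg_a), ("eeg_b", self.eeg_b),
        ):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")


def _rng(config: DyadConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, tag])


def _mean_reverting_walk(
    rng: np.random.Generator, n: int, dt: float, mean: float, std: float,
    tau: float = _DRIFT_TAU_S,
) -> np.ndarray:
    """AR(1) (discretized Ornstein-Uhlenbeck) walk with stationary SD `std`."""
    if std == 0.0:
        return np.full(n, mean)
    rho = np.exp(-dt / tau)
    innov = rng.standard_normal(n) * std * np.sqrt(1.0 - rho * rho)
    innov[0] = std * rng.standard_normal()  # stationary start
    x = sps.lfilter([1.0], [1.0, -rho], innov)
    return mean + x


def _integrate_free(w: np.ndarray, dt: float) -> np.ndarray:
    """Phase of an uncoupled oscillator: Euler integration of dphi = w dt."""
    phi = np.empty(w.size)
    phi[0] = 0.0
    np.cumsum(w[:-1] * dt, out=phi[1:])
    return phi


def _integrate_follower(
    w_f: np.ndarray, phi_l: np.ndarray, gain: float, d: int, dt: float
) -> np.ndarray:
    """Euler integration of a follower pulled toward the leader's delayed phase."""
    n = w_f.size
    phi = np.empty(n)
    phi[0] = 0.0
    wl = w_f.tolist()
    pl = phi_l.tolist()
    p = 0.0
    from math import sin
    for i in range(n - 1):
        target = pl[i - d] if i >= d else pl[0]
        p = p + dt * (wl[i] + gain * sin(target - p))
        phi[i + 1] = p
    return phi


def _integrate_joint(
    w_a: np.ndarray, w_b: np.ndarray, gain: float, d: int, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric bidirectional delayed coupling, half gain each way."""
    n = w_a.size
    phi_a = np.empty(n)
    phi_b = np.empty(n)
    phi_a[0] = phi_b[0] = 0.0
    wa, wb = w_a.tolist(), w_b.tolist()
    g = gain / 2.0
    pa = pb = 0.0
    la, lb = [0.0], [0.0]
    from math import sin
    for i in range(n - 1):
        ta = lb[i - d] if i >= d else lb[0]
        tb = la[i - d] if i >= d else la[0]
        pa = pa + dt * (wa[i] + g * sin(ta - pa))
        pb = pb + dt * (wb[i] + g * sin(tb - pb))
        la.append(pa)
        lb.append(pb)
        phi_a[i + 1] = pa
        phi_b[i + 1] = pb
    return phi_a, phi_b


def simulate_movement(config: DyadConfig) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the two participants' 2-D position traces.

    Returns ``(pos_a, pos_b)``, each of shape ``(n_motion, 2)``.  In the
    ``follower`` condition participant B adapts to A; in ``leader`` the
    roles are swapped; ``joint`` couples both ways at half strength.
    Deterministic given ``config.seed``.
    """
    n = config.n_motion
    dt = 1.0 / config.fs_motion

    f_a = _mean_reverting_walk(_rng(config, _STREAM_FREQ_A), n, dt,
                               config.base_freq, config.drift_std)
    f_b = _mean_reverting_walk(_rng(config, _STREAM_FREQ_B), n, dt,
                               config.base_freq, config.drift_std)
    w_a = 2.0 * np.pi * np.maximum(f_a, _FREQ_FLOOR_HZ)
    w_b = 2.0 * np.pi * np.maximum(f_b, _FREQ_FLOOR_HZ)

    gain = config.coupling_strength * 2.0 * np.pi * _COUPLING_GAIN_HZ
    d = int(round(config.follower_delay_s * config.fs_motion))

    if gain == 0.0:
        phi_a = _integrate_free(w_a, dt)
        phi_b = _integrate_free(w_b, dt)
    elif config.condition == "follower":
        phi_a = _integrate_free(w_a, dt)
        phi_b = _integrate_follower(w_b, phi_a, gain, d, dt)
    elif config.condition == "leader":
        phi_b = _integrate_free(w_b, dt)
        phi_a = _integrate_follower(w_a, phi_b, gain, d, dt)
    else:  # joint
        phi_a, phi_b = _integrate_joint(w_a, w_b, gain, d, dt)

    amp_a = np.abs(_mean_reverting_walk(_rng(config, _STREAM_AMP_A), n, dt,
                                        1.0, config.amp_drift_std))
    amp_b = np.abs(_mean_reverting_walk(_rng(config, _STREAM_AMP_B), n, dt,
                                        1.0, config.amp_drift_std))

    # motion axes tilted a few degrees off horizontal, as in real seating
    tilt_rng = _rng(config, _STREAM_TILT)
    theta_a, theta_b = np.deg2rad(tilt_rng.normal(10.0, 3.0, size=2))

    pos = []
    for amp, phi, theta, tag in (
        (amp_a, phi_a, theta_a, _STREAM_NOISE_A),
        (amp_b, phi_b, theta_b, _STREAM_NOISE_B),
    ):
        disp = amp * np.sin(phi)
        xy = np.column_stack([disp * np.cos(theta), disp * np.sin(theta)])
        if config.noise_rel > 0:
            xy += (config.noise_rel * float(np.mean(amp))
                   * _rng(config, tag).standard_normal(xy.shape))
        pos.append(xy)
    return pos[0], pos[1]


def _one_over_f_noise(
    rng: np.random.Generator, n_ch: int, n: int, fs: float, exponent: float
) -> np.ndarray:
    """Unit-variance Gaussian noise with a 1/f^exponent power spectrum.

    The spectrum is flattened below 0.1 Hz to avoid unbounded drifts.
    """
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    f_floor = 0.1
    shape = np.empty_like(f)
    shape[0] = 0.0
    shape[1:] = np.maximum(f[1:], f_floor) ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n=n, axis=1)
    x /= x.std(axis=1, keepdims=True)
    return x


def simulate_eeg(
    error: np.ndarray, config: DyadConfig, participant: int = 0
) -> np.ndarray:
    """Simulate an EEG array (``n_channels`` x ``n_eeg``) tracking `error`.

    The first ``n_tracking_channels`` channels contain the error signal
    circularly shifted by ``tracking_lag_s`` (positive = EEG lags error),
    optionally low-passed at ``tracking_band_hz``, scaled so the ratio of
    tracking power to background power equals ``tracking_snr``.  Remaining
    channels are 1/f background only.  All channels are mean-centered.
    Deterministic given ``config.seed`` and ``participant``.
    """
    values = np.asarray(getattr(error, "values", error), dtype=float).ravel()
    n = values.size
    if abs(config.tracking_lag_s) * config.fs_eeg >= n:
        raise ValueError("tracking_lag_s exceeds error duration")

    rng = np.random.default_rng(
        [int(config.seed) & 0x7FFFFFFF, _STREAM_EEG, int(participant)]
    )
    shift = int(round(config.tracking_lag_s * config.fs_eeg))
    tracked = np.roll(values, shift)
    if config.tracking_band_hz is not None:
        sos = sps.butter(4, config.tracking_band_hz, btype="lowpass",
                         fs=config.fs_eeg, output="sos")
        tracked = sps.sosfiltfilt(sos, tracked)
    tracked = tracked - tracked.mean()
    t_std = tracked.std()
    if t_std == 0:
        raise ValueError("error signal has zero variance; nothing to track")

    snr = config.tracking_snr
    if np.isinf(snr):
        eeg = np.zeros((config.n_channels, n))
        eeg[: config.n_tracking_channels] = tracked / t_std
    else:
        if snr < 0:
            raise ValueError("tracking_snr must be nonnegative")
        background = _one_over_f_noise(rng, config.n_channels, n,
                                       config.fs_eeg, config.background_exponent)
        eeg = background
        scale = np.sqrt(snr) / t_std  # background has unit variance
        eeg[: config.n_tracking_channels] += scale * tracked
    return eeg - eeg.mean(axis=1, keepdims=True)


def simulate_trial(config: DyadConfig) -> DyadTrial:
    """Simulate a full trial: movement, joint-PCA error, and both EEGs."""
    from .kinematics import compute_error, project_dyad

    pos_a, pos_b = simulate_movement(config)
    proj_a, proj_b = project_dyad(pos_a, pos_b)
    error = compute_error(proj_a, proj_b, config.fs_motion, config.fs_eeg,
                          condition=config.condition)
    eeg_a = simulate_eeg(error.values, config, participant=0)
    eeg_b = simulate_eeg(error.values, config, participant=1)
    return DyadTrial(pos_a=pos_a, pos_b=pos_b, eeg_a=eeg_a, eeg_b=eeg_b,
                     condition=config.condition, ground_truth=config)
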