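"""Self-other error and instantaneous-frequency signals from movement traces.

The self-other synchronization error is the absolute difference between the
two partners' positions projected onto a common principal movement axis.
The instantaneous-frequency control signal is the absolute rate of change
of the Hilbert instantaneous frequency of a single participant's movement,
which indexes movement adjustments (acceleration or deceleration)
irrespective of direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

__all__ = [
    "ErrorSeries",
    "InstFreqSeries",
    "principal_axis_project",
    "project_dyad",
    "compute_error",
    "instantaneous_freq_change",
]


@dataclass
class ErrorSeries:
    """Nonnegative self-other error sampled at the EEG rate."""

    values: np.ndarray
    fs: float
    trial_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("error values must be nonnegative")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("error values must be finite")


@dataclass
class InstFreqSeries:
    """|d/dt instantaneous frequency| in Hz/s."""

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("values must be nonnegative and finite")


def _principal_axis(pos: np.ndarray) -> np.ndarray:
    """First principal axis of a (n, d) point cloud, oriented so its
    loading on the nominal horizontal axis (column 0) is nonnegative."""
    centered = pos - pos.mean(axis=0)
    cov = centered.T @ centered / max(len(pos) - 1, 1)
    if np.trace(cov) <= 0:
        raise ValueError("degenerate input: zero spatial variance")
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, -1]
    # orient: nonnegative loading on the first nonzero component,
    # horizontal axis first
    for load in axis:
        if load != 0:
            if load < 0:
                axis = -axis
            break
    return axis


def principal_axis_project(pos: np.ndarray) -> np.ndarray:
    """Project a (n, d>=2) position trace onto its first principal axis.

    Returns the mean-centered scalar projection.  The axis is oriented so
    its loading on the nominal horizontal axis is nonnegative.
    """
    pos = np.asarray(pos, dtype=float)
    if pos.ndim != 2 or pos.shape[0] < 2 or pos.shape[1] < 2:
        raise ValueError("need >= 2 samples and >= 2 spatial axes")
    axis = _principal_axis(pos)
    return (pos - pos.mean(axis=0)) @ axis


def project_dyad(pos_a: np.ndarray, pos_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project both participants onto ONE common principal axis.

    The axis is fitted on the concatenated two-participant data and both
    traces are centered by the joint mean, so a constant positional offset
    between the partners survives into the error signal.
    """
    pos_a = np.asarray(pos_a, dtype=float)
    pos_b = np.asarray(pos_b, dtype=float)
    if pos_a.shape != pos_b.shape:
        raise ValueError("participant traces must have identical shape")
    stacked = np.vstack([pos_a, pos_b])
    axis = _principal_axis(stacked)
    center = stacked.mean(axis=0)
    return (pos_a - center) @ axis, (pos_b - center) @ axis


def _resample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    # kaiser beta 20: passband ripple < 1e-9 so constant offsets between
    # the two projections survive resampling to ~1e-6 relative
    if fs_in == fs_out:
        return x
    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    return sps.resample_poly(x, frac.numerator, frac.denominator,
                             window=("kaiser", 20.0))


def compute_error(
    proj_a: np.ndarray,
    proj_b: np.ndarray,
    fs_motion: float,
    fs_eeg: float,
    trial_id: str = "",
    condition: str = "",
) -> ErrorSeries:
    """Self-other error: |a - b| after band-limited resampling to fs_eeg.

    Both projections (assumed on a common axis; see :func:`project_dyad`)
    are polyphase-resampled from the motion rate to the EEG rate first and
    the absolute difference is taken on the resampled traces.
    """
    proj_a = np.asarray(proj_a, dtype=float)
    proj_b = np.asarray(proj_b, dtype=float)
    if proj_a.shape != proj_b.shape or proj_a.ndim != 1:
        raise ValueError("projections must be 1-D and of equal length")
    if fs_eeg < fs_motion:
        warnings.warn("fs_eeg < fs_motion: downsampling the error signal",
                      stacklevel=2)
    a = _resample(proj_a, fs_motion, fs_eeg)
    b = _resample(proj_b, fs_motion, fs_eeg)
    return ErrorSeries(values=np.abs(a - b), fs=fs_eeg,
                       trial_id=trial_id, condition=condition)


def instantaneous_freq_change(
    proj: np.ndarray, fs: float, edge_taper_s: float = 1.0,
    smooth_hz: float | None = 0.5,
) -> InstFreqSeries:
    """|d/dt of the Hilbert instantaneous frequency|, in Hz/s.

    The analytic-signal phase is unwrapped and differentiated (central
    differences) to the instantaneous frequency, differentiated once more,
    and rectified.  The instantaneous frequency is zero-phase low-passed at
    ``smooth_hz`` before the second derivative: the discrete analytic
    signal of a near-1 Hz oscillation carries ripple around twice the
    carrier frequency whose derivative would otherwise swamp the slow
    (sub-cycle-rate) frequency adjustments this control signal indexes.
    The first and last ``edge_taper_s`` seconds are tapered with a
    raised-cosine ramp to suppress Hilbert edge artifacts.
    """
    proj = np.asarray(proj, dtype=float)
    if proj.ndim != 1 or proj.size < 4:
        raise ValueError("need a 1-D series with >= 4 samples")
    if proj.std() == 0:
        raise ValueError("constant input: instantaneous phase undefined")
    analytic = sps.hilbert(proj - proj.mean())
    phase = np.unwrap(np.angle(analytic))
    f_inst = np.gradient(phase) * fs / (2.0 * np.pi)
    if smooth_hz is not None and smooth_hz < fs / 2:
        sos = sps.butter(4, smooth_hz, btype="lowpass", fs=fs, output="sos")
        f_inst = sps.sosfiltfilt(sos, f_inst)
    dfdt = np.abs(np.gradient(f_inst) * fs)

    n_edge = int(round(edge_taper_s * fs))
    if n_edge > 0 and 2 * n_edge < dfdt.size:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_edge) / n_edge))
        dfdt[:n_edge] *= ramp
        dfdt[-n_edge:] *= ramp[::-1]
    return InstFreqSeries(values=dfdt, fs=fs)
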