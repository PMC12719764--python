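"""Multitaper cross-spectral estimation and EEG-error coherence.

Coherence between each EEG channel and the self-other error signal is

    Coh(f) = |S_xy(f)| / sqrt(S_xx(f) * S_yy(f))

with auto-/cross-spectral densities pooled over all 5 s epochs (50%
overlap) and tapers of all trials of a condition before the magnitude is
taken ("coherence of the pooled CSD").  The default taper family is DPSS
(Slepian) with K = 3 tapers, i.e. time-bandwidth NW = (K+1)/2 = 2 and a
realized half-bandwidth of (K+1)/(2T) = 0.4 Hz for T = 5 s epochs; a
single Hanning taper is available as an option.  The frequency grid is
the FFT grid of the epoch length (0.2 Hz for 5 s), retained up to 10 Hz.

Cells where either auto-spectrum vanishes have undefined coherence and
propagate as NaN, never as zero; band averages skip them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import windows as spw

__all__ = [
    "SpectralEstimate",
    "CoherenceSpectrum",
    "epoch",
    "mt_csd",
    "coherence",
    "band_average",
    "coherence_power_ratio",
    "pool_spectra",
    "tapered_segments",
    "csd_from_segments",
    "pooled_coherence",
    "half_bandwidth_hz",
]

DEFAULT_EPOCH_S = 5.0
DEFAULT_OVERLAP = 0.5
DEFAULT_N_TAPERS = 3
DEFAULT_F_MAX = 10.0


@dataclass
class SpectralEstimate:
    """Pooled auto- and cross-spectral densities on a common grid."""

    freqs: np.ndarray          # (F,) Hz, strictly increasing
    S_xx: np.ndarray           # (n_ch, F) real, >= 0
    S_yy: np.ndarray           # (F,) real, >= 0
    S_xy: np.ndarray           # (n_ch, F) complex
    n_epochs: int
    n_tapers: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.S_xx < -1e-12) or np.any(self.S_yy < -1e-12):
            raise ValueError("auto-spectra must be nonnegative")

    @property
    def n_segments(self) -> int:
        return self.n_epochs * self.n_tapers


@dataclass
class CoherenceSpectrum:
    """Magnitude coherence in [0, 1] per channel per frequency.

    ``kind`` distinguishes genuine ("real") from trial-shuffled
    ("surrogate") estimates.  Undefined cells are NaN.
    """

    freqs: np.ndarray
    coh: np.ndarray            # (n_ch, F)
    kind: str = "real"
    condition: str = ""
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coh = np.atleast_2d(np.asarray(self.coh, dtype=float))
        finite = self.coh[np.isfinite(self.coh)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-9):
            raise ValueError("coherence must lie in [0, 1]")
        if self.kind not in ("real", "surrogate"):
            raise ValueError("kind must be 'real' or 'surrogate'")


def half_bandwidth_hz(n_tapers: int, epoch_len_s: float) -> float:
    """Realized spectral half-bandwidth of the DPSS family used here."""
    return (n_tapers + 1) / (2.0 * epoch_len_s)


def epoch(
    x: np.ndarray,
    fs: float,
    epoch_len_s: float = DEFAULT_EPOCH_S,
    overlap: float = DEFAULT_OVERLAP,
) -> np.ndarray:
    """Slice a series into overlapping epochs; trailing partial dropped.

    1-D input of length n -> (n_epochs, nper); channel x time input ->
    (n_epochs, n_ch, nper).
    """
    x = np.asarray(x, dtype=float)
    nper = int(round(epoch_len_s * fs))
    step = int(round(epoch_len_s * (1.0 - overlap) * fs))
    if nper <= 0 or step <= 0:
        raise ValueError("epoch length and advance must be positive")
    n = x.shape[-1]
    if n < nper:
        raise ValueError("series shorter than one epoch")
    starts = np.arange(0, n - nper + 1, step)
    out = np.stack([x[..., s:s + nper] for s in starts], axis=0)
    return out


def _tapers(nper: int, n_tapers: int, family: str) -> np.ndarray:
    """Unit-energy taper set of shape (K, nper)."""
    if family == "dpss":
        nw = (n_tapers + 1) / 2.0
        tap = spw.dpss(nper, nw, Kmax=n_tapers)
        tap = np.atleast_2d(tap)
    elif family == "hann":
        if n_tapers != 1:
            raise ValueError("hann family supports a single taper")
        w = spw.hann(nper, sym=False)
        tap = (w / np.linalg.norm(w))[None, :]
    else:
        raise ValueError(f"unknown taper family: {family}")
    # enforce unit energy per taper
    tap = tap / np.linalg.norm(tap, axis=1, keepdims=True)
    return tap


def _freq_mask(nper: int, fs: float, f_max: float | None) -> tuple[np.ndarray, np.ndarray]:
    freqs = np.fft.rfftfreq(nper, 1.0 / fs)
    if f_max is None:
        mask = np.ones(freqs.size, dtype=bool)
    else:
        mask = freqs <= f_max + 1e-9
    return freqs[mask], mask


def _taper_fft(epochs: np.ndarray, fs: float, n_tapers: int, f_max: float | None,
               taper: str) -> tuple[np.ndarray, np.ndarray]:
    """Scaled tapered FFT coefficients.

    epochs: (n_ep, ..., nper).  Returns (coeffs, freqs) with coeffs of
    shape (n_ep * K, ..., F); products of coefficients are one-sided
    spectral densities (units^2 / Hz).
    """
    epochs = np.asarray(epochs, dtype=float)
    nper = epochs.shape[-1]
    epochs = epochs - epochs.mean(axis=-1, keepdims=True)
    tap = _tapers(nper, n_tapers, taper)

    freqs_full = np.fft.rfftfreq(nper, 1.0 / fs)
    freqs, mask = _freq_mask(nper, fs, f_max)
    # one-sided density scaling baked into the coefficients
    scale = np.full(freqs_full.size, np.sqrt(2.0 / fs))
    scale[0] = np.sqrt(1.0 / fs)
    if nper % 2 == 0:
        scale[-1] = np.sqrt(1.0 / fs)
    scale = scale[mask]

    # (n_ep, K, ..., nper) -> FFT -> select bins
    shaped = np.expand_dims(epochs, 1) * tap.reshape(
        (1, tap.shape[0]) + (1,) * (epochs.ndim - 2) + (nper,)
    )
    coeffs = np.fft.rfft(shaped, axis=-1)[..., mask] * scale
    # merge epoch and taper axes into a single segment axis
    coeffs = coeffs.reshape((-1,) + coeffs.shape[2:])
    return coeffs, freqs


def tapered_segments(
    x: np.ndarray,
    fs: float,
    epoch_len_s: float = DEFAULT_EPOCH_S,
    overlap: float = DEFAULT_OVERLAP,
    n_tapers: int = DEFAULT_N_TAPERS,
    f_max: float | None = DEFAULT_F_MAX,
    taper: str = "dpss",
) -> tuple[np.ndarray, np.ndarray]:
    """Epoch a series and return its scaled tapered FFT coefficients.

    This is the cacheable primitive shared by the coherence, surrogate and
    lag-scan paths: every pooled spectral density is a mean of products of
    these coefficients.
    """
    eps = epoch(x, fs, epoch_len_s, overlap)
    return _taper_fft(eps, fs, n_tapers, f_max, taper)


def csd_from_segments(
    X: np.ndarray, Y: np.ndarray, freqs: np.ndarray, n_tapers: int = DEFAULT_N_TAPERS
) -> SpectralEstimate:
    """Pooled spectral estimate from coefficient arrays.

    X: (n_seg, n_ch, F) or (n_seg, F) EEG coefficients; Y: (n_seg, F)
    error coefficients.  Unequal segment counts are truncated to the
    shorter (relevant when cross-pairing trials of different lengths).
    """
    X = np.asarray(X)
    Y = np.asarray(Y)
    if X.ndim == 2:
        X = X[:, None, :]
    n_seg = min(X.shape[0], Y.shape[0])
    X, Y = X[:n_seg], Y[:n_seg]
    S_xx = np.mean(np.abs(X) ** 2, axis=0)
    S_yy = np.mean(np.abs(Y) ** 2, axis=0)
    S_xy = np.mean(X * np.conj(Y[:, None, :]), axis=0)
    return SpectralEstimate(freqs=freqs, S_xx=S_xx, S_yy=S_yy, S_xy=S_xy,
                            n_epochs=n_seg // n_tapers, n_tapers=n_tapers)


def mt_csd(
    eeg_epochs: np.ndarray,
    error_epochs: np.ndarray,
    fs: float,
    n_tapers: int = DEFAULT_N_TAPERS,
    f_max: float | None = DEFAULT_F_MAX,
    taper: str = "dpss",
) -> SpectralEstimate:
    """Multitaper auto-/cross-spectra pooled over epochs x tapers.

    ``eeg_epochs``: (n_ep, n_ch, nper) or (n_ep, nper); ``error_epochs``:
    (n_ep, nper).  Epochs are demeaned before tapering.
    """
    eeg_epochs = np.asarray(eeg_epochs, dtype=float)
    error_epochs = np.asarray(error_epochs, dtype=float)
    if eeg_epochs.ndim == 2:
        eeg_epochs = eeg_epochs[:, None, :]
    if (eeg_epochs.shape[0] != error_epochs.shape[0]
            or eeg_epochs.shape[-1] != error_epochs.shape[-1]):
        raise ValueError("EEG and error epochs must share count and length")
    X, freqs = _taper_fft(eeg_epochs, fs, n_tapers, f_max, taper)
    Y, _ = _taper_fft(error_epochs, fs, n_tapers, f_max, taper)
    return csd_from_segments(X, Y, freqs, n_tapers=n_tapers)


def pool_spectra(estimates: list[SpectralEstimate]) -> SpectralEstimate:
    """Pool spectral estimates across trials (segment-count weighted)."""
    if not estimates:
        raise ValueError("nothing to pool")
    freqs = estimates[0].freqs
    for se in estimates[1:]:
        if not np.allclose(se.freqs, freqs):
            raise ValueError("mismatched frequency grids")
    w = np.array([se.n_segments for se in estimates], dtype=float)
    wt = w / w.sum()
    S_xx = sum(wi * se.S_xx for wi, se in zip(wt, estimates))
    S_yy = sum(wi * se.S_yy for wi, se in zip(wt, estimates))
    S_xy = sum(wi * se.S_xy for wi, se in zip(wt, estimates))
    return SpectralEstimate(
        freqs=freqs, S_xx=S_xx, S_yy=S_yy, S_xy=S_xy,
        n_epochs=sum(se.n_epochs for se in estimates),
        n_tapers=estimates[0].n_tapers,
    )


def coherence(se: SpectralEstimate, kind: str = "real",
              condition: str = "") -> CoherenceSpectrum:
    """Magnitude coherence |S_xy| / sqrt(S_xx S_yy), NaN where undefined."""
    if se.n_segments < 1:
        raise ValueError("need at least one pooled segment")
    denom = np.sqrt(np.maximum(se.S_xx, 0.0) * np.maximum(se.S_yy, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(se.S_xy) / denom
    coh = np.where(denom > 0, coh, np.nan)
    coh = np.clip(coh, 0.0, 1.0)
    return CoherenceSpectrum(freqs=se.freqs, coh=coh, kind=kind, condition=condition)


def band_average(
    cs: CoherenceSpectrum, f_lo: float = 0.0, f_hi: float = 6.0
) -> np.ndarray:
    """Mean coherence per channel over [f_lo, f_hi] (inclusive), skipping NaN."""
    mask = (cs.freqs >= f_lo - 1e-9) & (cs.freqs <= f_hi + 1e-9)
    if not mask.any():
        raise ValueError("empty frequency band")
    sub = cs.coh[:, mask]
    with np.errstate(invalid="ignore"):
        out = np.nanmean(sub, axis=1)
    return out


def coherence_power_ratio(
    cs: CoherenceSpectrum,
    se: SpectralEstimate,
    band: tuple[float, float] | None = None,
) -> np.ndarray:
    """Coherence normalized by error power: coh(f) / S_yy(f).

    With ``band`` given, the per-frequency ratio is averaged over the band
    (NaN-skipping) and a (n_ch,) vector is returned; otherwise the full
    (n_ch, F) ratio array.
    """
    if not np.allclose(cs.freqs, se.freqs):
        raise ValueError("coherence and spectra must share the frequency grid")
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = cs.coh / se.S_yy[None, :]
    ratio = np.where(se.S_yy[None, :] > 0, ratio, np.nan)
    if band is None:
        return ratio
    mask = (cs.freqs >= band[0] - 1e-9) & (cs.freqs <= band[1] + 1e-9)
    if not mask.any():
        raise ValueError("empty frequency band")
    with np.errstate(invalid="ignore"):
        return np.nanmean(ratio[:, mask], axis=1)


def pooled_coherence(
    eeg_trials: list[np.ndarray] | np.ndarray,
    error_trials: list[np.ndarray] | np.ndarray,
    fs: float,
    condition: str = "",
    kind: str = "real",
    **spectral_kw,
) -> tuple[CoherenceSpectrum, SpectralEstimate]:
    """Condition-level coherence: pool CSDs over all trials, then normalize."""
    if isinstance(eeg_trials, np.ndarray) and eeg_trials.ndim <= 2:
        eeg_trials = [eeg_trials]
        error_trials = [error_trials]
    ests = []
    n_tapers = spectral_kw.get("n_tapers", DEFAULT_N_TAPERS)
    for eeg, err in zip(eeg_trials, error_trials, strict=True):
        X, freqs = tapered_segments(np.atleast_2d(eeg), fs, **spectral_kw)
        Y, _ = tapered_segments(np.asarray(err).ravel(), fs, **spectral_kw)
        ests.append(csd_from_segments(X, Y, freqs, n_tapers=n_tapers))
    se = pool_spectra(ests)
    return coherence(se, kind=kind, condition=condition), se
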