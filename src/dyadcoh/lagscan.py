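"""Time-lagged EEG-error coherence with peak magnitude/latency extraction.

For each lag tau on a uniform grid (default -2 s .. +2 s in 0.02 s steps,
201 lags), the error series is shifted so that EEG at time t is compared
with error at time t - tau; a positive peak lag therefore means brain
activity lags the error.  Lags are realized as exact integer-sample
shifts (0.02 s = 10 samples at 500 Hz); the non-overlapping ends are
truncated, the overlap is re-epoched, and coherence is computed with the
standard pooled multitaper settings and averaged over the 0-6 Hz band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectral import (
    DEFAULT_N_TAPERS,
    band_average,
    coherence,
    csd_from_segments,
    pool_spectra,
    tapered_segments,
)

__all__ = [
    "LagCoherenceProfile",
    "lag_grid",
    "lagged_coherence",
    "group_average",
    "movement_control_lagscan",
]


@dataclass
class LagCoherenceProfile:
    """Band-averaged coherence as a function of error time lag."""

    lags: np.ndarray           # (L,) seconds
    coh_band: np.ndarray       # (n_ch, L)
    group: str = ""
    condition: str = ""
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.coh_band = np.atleast_2d(np.asarray(self.coh_band, dtype=float))

    def _peak_index(self, row: np.ndarray) -> int:
        # ties: smallest |lag| first, then negative before positive
        finite = np.isfinite(row)
        if not finite.any():
            return -1
        best = np.nanmax(row)
        cand = np.flatnonzero(finite & (row == best))
        order = sorted(cand, key=lambda i: (abs(self.lags[i]), self.lags[i]))
        return order[0]

    @property
    def peak_coh(self) -> np.ndarray:
        """(n_ch,) maximum band coherence over lags (NaN if all undefined)."""
        out = np.full(self.coh_band.shape[0], np.nan)
        for c, row in enumerate(self.coh_band):
            i = self._peak_index(row)
            if i >= 0:
                out[c] = row[i]
        return out

    @property
    def peak_lag(self) -> np.ndarray:
        """(n_ch,) lag (s) attaining the maximum (NaN if all undefined)."""
        out = np.full(self.coh_band.shape[0], np.nan)
        for c, row in enumerate(self.coh_band):
            i = self._peak_index(row)
            if i >= 0:
                out[c] = self.lags[i]
        return out


def lag_grid(lag_min: float = -2.0, lag_max: float = 2.0,
             step: float = 0.02) -> np.ndarray:
    """Inclusive uniform lag grid; (-2, 2, 0.02) gives 201 lags."""
    if step <= 0:
        raise ValueError("step must be positive")
    if lag_min > lag_max:
        raise ValueError("lag_min must not exceed lag_max")
    n_lo = lag_min / step
    n_hi = lag_max / step
    if abs(n_lo - round(n_lo)) > 1e-9 or abs(n_hi - round(n_hi)) > 1e-9:
        raise ValueError("lag range endpoints must be multiples of step")
    return np.arange(round(n_lo), round(n_hi) + 1) * step


def _as_trials(x) -> list[np.ndarray]:
    if isinstance(x, (list, tuple)):
        return [np.asarray(getattr(t, "data", getattr(t, "values", t)), dtype=float)
                for t in x]
    return [np.asarray(getattr(x, "data", getattr(x, "values", x)), dtype=float)]


def lagged_coherence(
    eeg,
    error,
    lags: np.ndarray,
    fs: float,
    band: tuple[float, float] = (0.0, 6.0),
    group: str = "",
    condition: str = "",
    **spectral_kw,
) -> LagCoherenceProfile:
    """Band-averaged coherence per channel at each error time lag.

    ``eeg`` / ``error`` may be single trials (channel x time array or
    container with ``.data`` / ``.values``) or lists of trials; CSDs are
    pooled over trials per lag.  Positive lag compares EEG at t with
    error at t - lag (EEG lagging error).
    """
    eeg_trials = [np.atleast_2d(t) for t in _as_trials(eeg)]
    err_trials = [t.ravel() for t in _as_trials(error)]
    lags = np.asarray(lags, dtype=float)
    n_tapers = spectral_kw.get("n_tapers", DEFAULT_N_TAPERS)

    coh_band = np.full((eeg_trials[0].shape[0], lags.size), np.nan)
    for li, tau in enumerate(lags):
        shift = int(round(tau * fs))
        ests = []
        for x, y in zip(eeg_trials, err_trials):
            n = min(x.shape[1], y.size)
            if abs(shift) >= n:
                raise ValueError("lag exceeds trial duration")
            if shift >= 0:
                xs = x[:, shift:n]
                ys = y[: n - shift]
            else:
                xs = x[:, : n + shift]
                ys = y[-shift:n]
            X, freqs = tapered_segments(xs, fs, **spectral_kw)
            Y, _ = tapered_segments(ys, fs, **spectral_kw)
            ests.append(csd_from_segments(X, Y, freqs, n_tapers=n_tapers))
        cs = coherence(pool_spectra(ests), condition=condition)
        coh_band[:, li] = band_average(cs, *band)
    return LagCoherenceProfile(lags=lags, coh_band=coh_band, group=group,
                               condition=condition)


def group_average(
    profile: LagCoherenceProfile, groups: dict[str, list[int]]
) -> dict[str, LagCoherenceProfile]:
    """Average lag profiles within channel groups, then re-extract peaks.

    ``groups`` maps a group label to member channel indices; groups must
    be non-empty and index existing channels.
    """
    out: dict[str, LagCoherenceProfile] = {}
    for name, members in groups.items():
        if len(members) == 0:
            raise ValueError(f"empty channel group: {name}")
        sub = profile.coh_band[np.asarray(members, dtype=int)]
        mean = np.nanmean(sub, axis=0, keepdims=True)
        out[name] = LagCoherenceProfile(
            lags=profile.lags, coh_band=mean, group=name,
            condition=profile.condition,
        )
    return out


def movement_control_lagscan(
    ifs,
    error,
    lags: np.ndarray,
    fs: float,
    **kw,
) -> LagCoherenceProfile:
    """Lag scan of the instantaneous-frequency-change movement control.

    Identical to :func:`lagged_coherence` with the |d f_inst / dt| series
    standing in as a single "channel".  A (near-)constant control signal
    has undefined coherence; the profile is then NaN and the peak fields
    propagate NaN as the degenerate-control flag.
    """
    vals = [t.ravel() for t in _as_trials(ifs)]
    if all(float(np.std(v)) < 1e-12 * max(1.0, float(np.max(np.abs(v), initial=0.0)))
           or float(np.std(v)) == 0.0 for v in vals):
        lags = np.asarray(lags, dtype=float)
        return LagCoherenceProfile(lags=lags,
                                   coh_band=np.full((1, lags.size), np.nan),
                                   group=kw.pop("group", "ifs_control"))
    return lagged_coherence(ifs, error, lags, fs,
                            group=kw.pop("group", "ifs_control"), **kw)
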