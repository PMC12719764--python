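"""Trial-shuffled surrogate baseline for EEG-error coherence.

Chance-level coherence is estimated by pairing each trial's EEG with the
error series of a *different* trial of the same condition.  The pairings
are all derangements (fixed-point-free permutations) of the trial indices
-- 9 for the canonical 4 trials per condition -- so no error series ever
meets its own EEG, which would leak genuine coherence into the baseline.
Coherence is computed for each pairing with the same pooled-CSD settings
as the real estimate and averaged over pairings and conditions into one
baseline spectrum per participant per channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .spectral import (
    DEFAULT_N_TAPERS,
    CoherenceSpectrum,
    coherence,
    csd_from_segments,
    pool_spectra,
    tapered_segments,
)

__all__ = ["PermutationScheme", "enumerate_derangements", "surrogate_coherence"]


@dataclass
class PermutationScheme:
    """All fixed-point-free trial pairings for ``n_trials`` trials."""

    n_trials: int
    pairings: list[tuple[int, ...]]

    def __post_init__(self) -> None:
        seen = set()
        for p in self.pairings:
            if sorted(p) != list(range(self.n_trials)):
                raise ValueError(f"{p} is not a permutation of 0..{self.n_trials - 1}")
            if any(i == j for i, j in enumerate(p)):
                raise ValueError(f"{p} has a fixed point")
            if p in seen:
                raise ValueError(f"duplicate pairing {p}")
            seen.add(p)


def enumerate_derangements(n: int) -> PermutationScheme:
    """All derangements of {0..n-1} in lexicographic order (9 for n = 4)."""
    if n < 2:
        raise ValueError("need at least 2 trials to derange")
    pairings = [p for p in permutations(range(n))
                if all(i != j for i, j in enumerate(p))]
    return PermutationScheme(n_trials=n, pairings=pairings)


def surrogate_coherence(
    eeg_trials: list[np.ndarray],
    error_trials: list[np.ndarray],
    conditions: list[str] | None = None,
    scheme: PermutationScheme | None = None,
    fs: float | None = None,
    **spectral_kw,
) -> CoherenceSpectrum:
    """Baseline coherence from deranged EEG/error trial pairings.

    ``eeg_trials[i]`` (channel x time) and ``error_trials[i]`` belong to
    the same trial; ``conditions[i]`` groups trials (one group if None).
    For every condition and every derangement, coherence is computed
    between each trial's EEG and the deranged trial's error (CSDs pooled
    over the condition's trials, as in the real pipeline), then averaged
    over derangements and conditions.  Trials of unequal length are
    truncated to the shorter member of each pairing.
    """
    if fs is None:
        raise ValueError("fs is required")
    n = len(eeg_trials)
    if n != len(error_trials):
        raise ValueError("EEG and error trial lists must have equal length")
    if conditions is None:
        conditions = [""] * n
    n_tapers = spectral_kw.get("n_tapers", DEFAULT_N_TAPERS)

    # cache tapered coefficients once per trial
    X, Y, freqs = [], [], None
    lengths = set()
    for eeg, err in zip(eeg_trials, error_trials):
        xi, freqs = tapered_segments(np.atleast_2d(eeg), fs, **spectral_kw)
        yi, _ = tapered_segments(np.asarray(getattr(err, "values", err)).ravel(),
                                 fs, **spectral_kw)
        lengths.add(xi.shape[0])
        X.append(xi)
        Y.append(yi)
    if len(lengths) > 1:
        warnings.warn("unequal trial lengths: cross-pairings truncated to the "
                      "shorter trial", stacklevel=2)

    spectra = []
    for cond in dict.fromkeys(conditions):  # preserve order, unique
        idx = [i for i, c in enumerate(conditions) if c == cond]
        sch = scheme if scheme is not None else enumerate_derangements(len(idx))
        if sch.n_trials != len(idx):
            raise ValueError("scheme size does not match trials per condition")
        for pairing in sch.pairings:
            ests = [
                csd_from_segments(X[idx[i]], Y[idx[j]], freqs, n_tapers=n_tapers)
                for i, j in enumerate(pairing)
            ]
            cs = coherence(pool_spectra(ests), kind="surrogate", condition=str(cond))
            spectra.append(cs.coh)
    baseline = np.nanmean(np.stack(spectra, axis=0), axis=0)
    return CoherenceSpectrum(freqs=freqs, coh=baseline, kind="surrogate")
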