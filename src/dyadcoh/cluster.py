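"""Cluster-based permutation statistics along the frequency axis.

Point-wise statistics (paired t or Pearson correlation t) are thresholded
at the two-sided parametric critical value; maximal runs of contiguous
supra-threshold frequencies form clusters whose mass is the sum of
absolute statistics.  The familywise-corrected p-value of each cluster is
the proportion of permutations (random sign flips of the paired
differences, or subject-label shuffles for correlations) whose *maximum*
cluster mass exceeds the observed mass; permutations with no
supra-threshold cluster contribute a maximum mass of zero.  The default
p-value convention is add-one, (b + 1) / (m + 1), which can never be
exactly zero; the raw proportion b / m is available via
``p_convention="raw"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import stats as sstats

__all__ = [
    "ClusterResult",
    "pointwise_paired_t",
    "pointwise_correlation",
    "cluster_permutation",
]


@dataclass
class Cluster:
    start: int                 # first frequency index (inclusive)
    stop: int                  # last frequency index (inclusive)
    mass: float                # sum of |stat| over the run
    p_value: float
    freq_lo: float = np.nan
    freq_hi: float = np.nan


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    stat_series: np.ndarray
    threshold: float
    n_permutations: int
    null_max_mass: np.ndarray  # (n_permutations,)

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value <= alpha]


def _paired_t_from_diff(d: np.ndarray) -> np.ndarray:
    """Vectorized paired t over axis 0 of a (n, F) difference matrix.

    Zero-variance columns yield +/-inf (or 0 when the mean is also 0).
    """
    n = d.shape[0]
    mean = np.nanmean(d, axis=0)
    with np.errstate(invalid="ignore"):
        sd = np.nanstd(d, axis=0, ddof=1)
    counts = np.sum(np.isfinite(d), axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(counts))
        t = np.where((sd == 0) & (mean != 0), np.sign(mean) * np.inf, t)
        t = np.where((sd == 0) & (mean == 0), 0.0, t)
        t = np.where(counts < 2, np.nan, t)
    return t


def pointwise_paired_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Paired t statistic per frequency; (n_subj, F) inputs, NaN pairs dropped.

    Zero variance of the differences with nonzero mean is flagged as
    +/-inf, which counts as supra-threshold during cluster formation.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("paired inputs must share shape")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 paired subjects")
    d = a - b
    d = np.where(np.isfinite(a) & np.isfinite(b), d, np.nan)
    return _paired_t_from_diff(d)


def _corr_t(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise Pearson r and its t statistic for (n, F) inputs."""
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    sx = np.sqrt((xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc * yc).sum(axis=0) / (sx * sy)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    r = np.where((sx == 0) | (sy == 0), np.nan, r)
    t = np.where(np.isfinite(r), t, np.nan)
    return r, t


def pointwise_correlation(
    x: np.ndarray, y: np.ndarray, return_r: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Pearson correlation per frequency with its t statistic.

    Constant columns give an undefined correlation (NaN), treated as
    sub-threshold downstream.  Returns the t series, or (r, t) when
    ``return_r`` is set.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape != y.shape:
        raise ValueError("inputs must share shape")
    if x.shape[0] < 4:
        raise ValueError("need at least 4 subjects per frequency")
    r, t = _corr_t(x, y)
    return (r, t) if return_r else t


def _clusters_from_stat(stat: np.ndarray, threshold: float) -> list[tuple[int, int, float]]:
    """Maximal runs of contiguous |stat| > threshold (NaN = sub-threshold)."""
    with np.errstate(invalid="ignore"):
        supra = np.abs(stat) > threshold
    supra &= ~np.isnan(stat)
    out = []
    i = 0
    F = stat.size
    while i < F:
        if supra[i]:
            j = i
            while j + 1 < F and supra[j + 1]:
                j += 1
            out.append((i, j, float(np.sum(np.abs(stat[i:j + 1])))))
            i = j + 1
        else:
            i += 1
    return out


def _max_mass(stat: np.ndarray, threshold: float) -> float:
    cl = _clusters_from_stat(stat, threshold)
    return max((m for _, _, m in cl), default=0.0)


def cluster_permutation(
    stat_series: np.ndarray,
    subject_data,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    kind: str = "paired",
    freqs: np.ndarray | None = None,
    exact: bool = False,
    p_convention: str = "add_one",
) -> ClusterResult:
    """Cluster correction of a per-frequency statistic by permutation.

    ``kind="paired"``: ``subject_data`` is the (n_subj, F) matrix of
    paired differences; the null flips each subject's sign.  With
    ``exact=True`` all 2^n sign patterns are enumerated (n <= 20).
    ``kind="correlation"``: ``subject_data`` is an ``(x, y)`` tuple of
    (n_subj, F) matrices; the null shuffles subject labels of ``y``
    (sign flips are undefined for correlations).

    The cluster-defining threshold is the two-sided parametric critical
    value at ``alpha``.  Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if p_convention not in ("add_one", "raw"):
        raise ValueError("p_convention must be 'add_one' or 'raw'")
    stat_series = np.asarray(stat_series, dtype=float)
    rng = np.random.default_rng(seed)

    if kind == "paired":
        d = np.atleast_2d(np.asarray(subject_data, dtype=float))
        n = d.shape[0]
        threshold = float(sstats.t.ppf(1.0 - alpha / 2.0, df=n - 1))
        if exact:
            if n > 20:
                raise ValueError("exact enumeration limited to n <= 20 subjects")
            signs = np.array(list(product((-1.0, 1.0), repeat=n)))
        else:
            signs = rng.choice((-1.0, 1.0), size=(n_perm, n))
        null = np.empty(signs.shape[0])
        for i, s in enumerate(signs):
            null[i] = _max_mass(_paired_t_from_diff(d * s[:, None]), threshold)
    elif kind == "correlation":
        x, y = subject_data
        x = np.atleast_2d(np.asarray(x, dtype=float))
        y = np.atleast_2d(np.asarray(y, dtype=float))
        n = x.shape[0]
        threshold = float(sstats.t.ppf(1.0 - alpha / 2.0, df=n - 2))
        if exact:
            raise ValueError("exact enumeration is only supported for kind='paired'")
        null = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(n)
            _, t = _corr_t(x, y[perm])
            null[i] = _max_mass(t, threshold)
    else:
        raise ValueError("kind must be 'paired' or 'correlation'")

    m = null.size
    clusters = []
    for start, stop, mass in _clusters_from_stat(stat_series, threshold):
        b = int(np.sum(null >= mass))  # inf >= inf holds, so all-inf nulls give p = 1
        if p_convention == "add_one":
            p = (b + 1) / (m + 1)
        else:
            p = b / m
        clusters.append(Cluster(
            start=start, stop=stop, mass=mass, p_value=float(p),
            freq_lo=float(freqs[start]) if freqs is not None else np.nan,
            freq_hi=float(freqs[stop]) if freqs is not None else np.nan,
        ))
    return ClusterResult(clusters=clusters, stat_series=stat_series,
                         threshold=threshold, n_permutations=m,
                         null_max_mass=null)
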