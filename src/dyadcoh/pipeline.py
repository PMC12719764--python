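"""End-to-end orchestration: simulate -> analyze -> stats -> summarize.

Each stage reads only the previous stage's files in the run directory and
writes its own, so a run is reproducible and every number is traceable to
the echoed configuration and the single global seed.  The seed is fanned
out per dyad / condition / trial through ``numpy.random.SeedSequence`` so
stages and trials draw from independent streams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .cluster import cluster_permutation, pointwise_paired_t
from .kinematics import compute_error, instantaneous_freq_change, project_dyad
from .lagscan import group_average, lag_grid, lagged_coherence, movement_control_lagscan
from .spectral import band_average, coherence_power_ratio, pooled_coherence
from .surrogate import surrogate_coherence
from .synthetic import CONDITIONS, DyadConfig, simulate_trial

__all__ = ["RunConfig", "run_pipeline", "summarize"]

STAGES = ("simulate", "analyze", "stats")


@dataclass
class RunConfig:
    """Settings for a full pipeline run."""

    dyad: DyadConfig = field(default_factory=DyadConfig)
    n_dyads: int = 4
    n_trials: int = 4
    conditions: tuple[str, ...] = CONDITIONS
    # spectral settings
    epoch_len_s: float = 5.0
    overlap: float = 0.5
    n_tapers: int = 3
    f_max: float = 10.0
    band: tuple[float, float] = (0.0, 6.0)
    # lag-scan settings
    lag_min: float = -2.0
    lag_max: float = 2.0
    lag_step: float = 0.02
    channel_groups: dict[str, list[int]] | None = None
    # stats settings
    n_perm: int = 1000
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "dyadcoh_run"
    stages: tuple[str, ...] = STAGES
    # per-condition ground-truth overrides (e.g. follower tracks more
    # strongly and at a longer latency than leader)
    tracking_snr_by_condition: dict[str, float] | None = None
    tracking_lag_by_condition: dict[str, float] | None = None
    run_ifs_control: bool = True

    def __post_init__(self) -> None:
        if self.n_dyads < 1 or self.n_trials < 2:
            raise ValueError("need >= 1 dyad and >= 2 trials per condition")
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage: {s}")
        if not (0 < self.epoch_len_s and 0 <= self.overlap < 1):
            raise ValueError("invalid epoching settings")
        lag_grid(self.lag_min, self.lag_max, self.lag_step)  # validates
        if self.n_perm < 1 or not 0 < self.alpha < 1:
            raise ValueError("invalid stats settings")

    def spectral_kw(self) -> dict:
        return dict(epoch_len_s=self.epoch_len_s, overlap=self.overlap,
                    n_tapers=self.n_tapers, f_max=self.f_max)

    def to_yaml(self, path: Path) -> None:
        d = dataclasses.asdict(self)
        d["dyad"] = dataclasses.asdict(self.dyad)
        path.write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "dyad" in d and isinstance(d["dyad"], dict):
            d["dyad"] = DyadConfig(**d["dyad"])
        for key in ("conditions", "stages", "band"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def _trial_seed(seed: int, dyad: int, cond_i: int, trial: int) -> int:
    ss = np.random.SeedSequence([seed, dyad, cond_i, trial])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing {path.name}: run the '{producer}' stage first"
        )
    return path


def _stage_simulate(cfg: RunConfig, out: Path) -> None:
    trials = []
    for d in range(cfg.n_dyads):
        for ci, cond in enumerate(cfg.conditions):
            over = {}
            if cfg.tracking_snr_by_condition:
                over["tracking_snr"] = cfg.tracking_snr_by_condition[cond]
            if cfg.tracking_lag_by_condition:
                over["tracking_lag_s"] = cfg.tracking_lag_by_condition[cond]
            for k in range(cfg.n_trials):
                tc = cfg.dyad.replace(
                    condition=cond, seed=_trial_seed(cfg.seed, d, ci, k), **over
                )
                trials.append(simulate_trial(tc))
    dio.save_trials(out / "trials.h5", trials)
    dio.movement_to_csv(out / "movement.csv", trials)


def _participants(cfg: RunConfig, trials):
    """Yield (participant_id, condition, eeg trials, error trials, motion proj)."""
    per = cfg.n_trials * len(cfg.conditions)
    for d in range(cfg.n_dyads):
        block = trials[d * per:(d + 1) * per]
        for side in ("a", "b"):
            pid = f"d{d:02d}{side}"
            for ci, cond in enumerate(cfg.conditions):
                sub = block[ci * cfg.n_trials:(ci + 1) * cfg.n_trials]
                eegs, errs, projs = [], [], []
                for tr in sub:
                    pa, pb = project_dyad(tr.pos_a, tr.pos_b)
                    err = compute_error(pa, pb, tr.ground_truth.fs_motion,
                                        tr.ground_truth.fs_eeg, condition=cond)
                    eegs.append(tr.eeg_a if side == "a" else tr.eeg_b)
                    errs.append(err.values)
                    projs.append(pa if side == "a" else pb)
                yield pid, cond, eegs, errs, projs, sub[0].ground_truth


def _stage_analyze(cfg: RunConfig, out: Path) -> None:
    trials = dio.load_trials(_require(out / "trials.h5", "simulate"))
    fs = cfg.dyad.fs_eeg
    lags = lag_grid(cfg.lag_min, cfg.lag_max, cfg.lag_step)
    groups = cfg.channel_groups or {
        "tracking": list(range(cfg.dyad.n_tracking_channels)),
        "background": list(range(cfg.dyad.n_tracking_channels, cfg.dyad.n_channels)),
    }
    skw = cfg.spectral_kw()

    coh_rows, band_rows, lag_rows, peak_rows = [], [], [], []
    per_participant: dict[str, dict] = {}
    for pid, cond, eegs, errs, projs, gt in _participants(cfg, trials):
        rec = per_participant.setdefault(pid, {"eeg": [], "err": [], "cond": []})
        rec["eeg"].extend(eegs)
        rec["err"].extend(errs)
        rec["cond"].extend([cond] * len(eegs))

        cs, se = pooled_coherence(eegs, errs, fs, condition=cond, **skw)
        for ch in range(cs.coh.shape[0]):
            for fi, f in enumerate(cs.freqs):
                coh_rows.append((pid, cond, ch, float(f), float(cs.coh[ch, fi]), "real"))
        bavg = band_average(cs, *cfg.band)
        ratio = coherence_power_ratio(cs, se, band=cfg.band)
        for ch in range(bavg.size):
            band_rows.append((pid, cond, ch, float(bavg[ch]), float(ratio[ch]), "real"))

        prof = lagged_coherence(eegs, errs, lags, fs, band=cfg.band,
                                condition=cond, **skw)
        for gname, gprof in group_average(prof, groups).items():
            for li, lag in enumerate(gprof.lags):
                lag_rows.append((pid, cond, gname, float(lag),
                                 float(gprof.coh_band[0, li])))
            peak_rows.append((pid, cond, gname, float(gprof.peak_coh[0]),
                              float(gprof.peak_lag[0])))

        if cfg.run_ifs_control:
            ifs = [instantaneous_freq_change(p, gt.fs_motion).values for p in projs]
            # bring the motion-rate control to the EEG rate via the error
            # pathway used everywhere else
            from .kinematics import _resample
            ifs = [np.abs(_resample(v, gt.fs_motion, fs)) for v in ifs]
            n = min(len(v) for v in ifs)
            cprof = movement_control_lagscan([v[:n] for v in ifs],
                                             [e[:n] for e in errs],
                                             lags, fs, band=cfg.band, **skw)
            for li, lag in enumerate(cprof.lags):
                lag_rows.append((pid, cond, "ifs_control", float(lag),
                                 float(cprof.coh_band[0, li])))
            peak_rows.append((pid, cond, "ifs_control",
                              float(cprof.peak_coh[0]), float(cprof.peak_lag[0])))

    # one surrogate baseline per participant, averaged over derangements
    # and conditions
    for pid, rec in per_participant.items():
        cs = surrogate_coherence(rec["eeg"], rec["err"], conditions=rec["cond"],
                                 fs=fs, **skw)
        for ch in range(cs.coh.shape[0]):
            for fi, f in enumerate(cs.freqs):
                coh_rows.append((pid, "all", ch, float(f),
                                 float(cs.coh[ch, fi]), "surrogate"))
        bavg = band_average(cs, *cfg.band)
        for ch in range(bavg.size):
            band_rows.append((pid, "all", ch, float(bavg[ch]), np.nan, "surrogate"))

    pd.DataFrame(coh_rows, columns=["participant", "condition", "channel",
                                    "frequency", "coherence", "kind"]
                 ).to_csv(out / "coherence.csv", index=False)
    pd.DataFrame(band_rows, columns=["participant", "condition", "channel",
                                     "band_coherence", "band_ratio", "kind"]
                 ).to_csv(out / "band_avg.csv", index=False)
    pd.DataFrame(lag_rows, columns=["participant", "condition", "group",
                                    "lag", "coherence"]
                 ).to_csv(out / "lagscan.csv", index=False)
    pd.DataFrame(peak_rows, columns=["participant", "condition", "group",
                                     "peak_coh", "peak_lag"]
                 ).to_csv(out / "peaks.csv", index=False)


def _stage_stats(cfg: RunConfig, out: Path) -> None:
    coh = pd.read_csv(_require(out / "coherence.csv", "analyze"))
    real = (coh[coh["kind"] == "real"]
            .groupby(["participant", "frequency"])["coherence"].mean().unstack())
    surr = (coh[coh["kind"] == "surrogate"]
            .groupby(["participant", "frequency"])["coherence"].mean().unstack())
    surr = surr.loc[real.index, real.columns]
    freqs = real.columns.to_numpy(dtype=float)
    a, b = real.to_numpy(), surr.to_numpy()
    t = pointwise_paired_t(a, b)
    res = cluster_permutation(t, a - b, n_perm=cfg.n_perm, alpha=cfg.alpha,
                              seed=cfg.seed, kind="paired", freqs=freqs)
    report = {
        "comparison": "real_vs_surrogate",
        "n_participants": int(a.shape[0]),
        "threshold": res.threshold,
        "n_permutations": res.n_permutations,
        "clusters": [dataclasses.asdict(c) for c in res.clusters],
    }
    (out / "clusters.json").write_text(json.dumps(report, indent=2))


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured stages; returns the manifest dictionary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    manifest: dict = {"seed": cfg.seed, "stages": {}, "files": {}}
    runners = {"simulate": _stage_simulate, "analyze": _stage_analyze,
               "stats": _stage_stats}
    try:
        for stage in cfg.stages:
            runners[stage](cfg, out)
            manifest["stages"][stage] = "ok"
    except Exception as exc:
        manifest["stages"][stage] = f"failed: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    for f in sorted(out.glob("*.csv")) + sorted(out.glob("*.json")):
        if f.name != "manifest.json":
            manifest["files"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def summarize(results_dir: str | Path) -> pd.DataFrame:
    """Condition x measure table from a completed run directory."""
    out = Path(results_dir)
    band_path = out / "band_avg.csv"
    if not out.exists() or not band_path.exists():
        raise FileNotFoundError(f"no completed runs found under {out}")
    band = pd.read_csv(band_path)
    real = band[band["kind"] == "real"]
    rows = []
    peaks = pd.read_csv(out / "peaks.csv") if (out / "peaks.csv").exists() else None
    for cond, sub in real.groupby("condition"):
        row = {
            "condition": cond,
            "band_coherence": sub["band_coherence"].mean(),
            "band_ratio": sub["band_ratio"].mean(),
        }
        if peaks is not None:
            for g, gsub in peaks[peaks["condition"] == cond].groupby("group"):
                row[f"peak_coh[{g}]"] = gsub["peak_coh"].mean()
                row[f"peak_lag[{g}]"] = gsub["peak_lag"].mean()
        rows.append(row)
    surr = band[band["kind"] == "surrogate"]
    if len(surr):
        rows.append({"condition": "surrogate_baseline",
                     "band_coherence": surr["band_coherence"].mean(),
                     "band_ratio": np.nan})
    if not rows:
        raise ValueError("no runs found: band_avg.csv is empty")
    return pd.DataFrame(rows).set_index("condition")
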