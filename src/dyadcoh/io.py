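"""Trial container I/O: HDF5 round-trip, CSV export, YAML configuration.

One HDF5 file holds a run's trials under ``/motion`` and ``/eeg`` groups
with a ``/meta`` group carrying each trial's ground-truth configuration,
so every derived number is traceable to its generating parameters.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .synthetic import DyadConfig, DyadTrial

__all__ = ["save_trials", "load_trials", "movement_to_csv", "load_config"]


def save_trials(path: str | Path, trials: list[DyadTrial]) -> None:
    """Write trials to one HDF5 container (/motion, /eeg, /meta)."""
    with h5py.File(path, "w") as f:
        motion = f.create_group("motion")
        eeg = f.create_group("eeg")
        meta = f.create_group("meta")
        for i, tr in enumerate(trials):
            key = f"trial{i:03d}"
            g = motion.create_group(key)
            g.create_dataset("pos_a", data=tr.pos_a)
            g.create_dataset("pos_b", data=tr.pos_b)
            g = eeg.create_group(key)
            g.create_dataset("eeg_a", data=tr.eeg_a)
            g.create_dataset("eeg_b", data=tr.eeg_b)
            meta.attrs[key] = json.dumps({
                "condition": tr.condition,
                "config": dataclasses.asdict(tr.ground_truth),
            })


def load_trials(path: str | Path) -> list[DyadTrial]:
    """Read trials back from :func:`save_trials` output."""
    trials = []
    with h5py.File(path, "r") as f:
        keys = sorted(f["motion"].keys())
        for key in keys:
            meta = json.loads(f["meta"].attrs[key])
            cfg = DyadConfig(**meta["config"])
            trials.append(DyadTrial(
                pos_a=f["motion"][key]["pos_a"][...],
                pos_b=f["motion"][key]["pos_b"][...],
                eeg_a=f["eeg"][key]["eeg_a"][...],
                eeg_b=f["eeg"][key]["eeg_b"][...],
                condition=meta["condition"],
                ground_truth=cfg,
            ))
    return trials


def movement_to_csv(path: str | Path, trials: list[DyadTrial]) -> None:
    """Long-format CSV of the raw movement traces."""
    frames = []
    for i, tr in enumerate(trials):
        n = tr.pos_a.shape[0]
        t = np.arange(n) / tr.ground_truth.fs_motion
        frames.append(pd.DataFrame({
            "trial": i,
            "condition": tr.condition,
            "time_s": t,
            "pos_a_x": tr.pos_a[:, 0], "pos_a_y": tr.pos_a[:, 1],
            "pos_b_x": tr.pos_b[:, 0], "pos_b_y": tr.pos_b[:, 1],
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_config(path: str | Path) -> DyadConfig:
    """Build a DyadConfig from a YAML/JSON key-value file."""
    text = Path(path).read_text()
    mapping = yaml.safe_load(text)
    if not isinstance(mapping, dict):
        raise ValueError("config file must contain a key-value mapping")
    valid = {f.name for f in dataclasses.fields(DyadConfig)}
    unknown = set(mapping) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return DyadConfig(**mapping)
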