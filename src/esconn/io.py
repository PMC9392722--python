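"""On-disk formats: HDF5 trial/series containers, TSV tables, YAML configs,
JSON provenance.  All tables are UTF-8 TSV with header rows; every container
records the master seed used to create it."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd
import yaml

from .containers import CHANNEL_COLUMNS, BoldRun, TrialSet


def spawn_seeds(master_seed: int, n: int) -> list:
    """Deterministically derive per-stage seeds (< 2**31) from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


# ---------------------------------------------------------------------------
# trial containers
# ---------------------------------------------------------------------------

def write_trials(path, trials: TrialSet) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=trials.data)
        d.attrs["dims"] = "channels x trials x samples"
        f.attrs["fs"] = trials.fs
        f.attrs["t0_index"] = trials.t0_index
        f.attrs["stim_group"] = trials.stim_group
        f.attrs["run_id"] = trials.run_id
        if trials.seed is not None:
            f.attrs["seed"] = trials.seed
        f.create_dataset("channel_names",
                         data=np.array(trials.channels["name"], dtype="S"))


def write_channels(path, channels: pd.DataFrame) -> None:
    channels.to_csv(path, sep="\t", index=False)


def read_channels(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    missing = [c for c in CHANNEL_COLUMNS if c not in tab.columns]
    if missing:
        raise ValueError(f"channel table {path} missing columns: {missing}")
    return tab


def read_trials(path, channel_table) -> TrialSet:
    """Load a trial container and join channel annotations by channel name.

    Annotation rows for unrecorded channels are accepted with a warning;
    a recorded channel missing from the table is an error naming it.
    Unknown ROI labels map to roi_group ``other``.
    """
    import warnings

    if isinstance(channel_table, (str, Path)):
        channel_table = read_channels(channel_table)
    with h5py.File(path, "r") as f:
        for key in ("fs", "t0_index", "stim_group", "run_id"):
            if key not in f.attrs:
                raise ValueError(f"trial container {path}: missing attribute {key!r}")
        if "data" not in f or f["data"].ndim != 3:
            raise ValueError(f"trial container {path}: dataset 'data' must be 3-D")
        data = f["data"][()]
        names = [n.decode() for n in f["channel_names"][()]]
        fs = float(f.attrs["fs"])
        t0 = int(f.attrs["t0_index"])
        stim_group = str(f.attrs["stim_group"])
        run_id = str(f.attrs["run_id"])
        seed = int(f.attrs["seed"]) if "seed" in f.attrs else None
    tab = channel_table.set_index("name")
    missing = [n for n in names if n not in tab.index]
    if missing:
        raise ValueError(f"channel table is missing recorded channels: {missing}")
    extra = [n for n in tab.index if n not in names]
    if extra:
        warnings.warn(f"channel table lists unrecorded channels: {extra}")
    ordered = tab.loc[names].reset_index()
    return TrialSet(data=data, fs=fs, t0_index=t0, channels=ordered,
                    stim_group=stim_group, run_id=run_id, seed=seed)


# ---------------------------------------------------------------------------
# BOLD containers
# ---------------------------------------------------------------------------

def write_bold(path, run: BoldRun) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("series", data=run.series)
        f.create_dataset("fd", data=run.fd)
        f.create_dataset("onsets", data=np.asarray(run.onsets))
        f.create_dataset("roi_names", data=np.array(run.roi_names, dtype="S"))
        f.attrs.update(dict(tr=run.tr, frames_on=run.frames_on,
                            frames_off=run.frames_off, stim_group=run.stim_group,
                            run_id=run.run_id))
        if run.seed is not None:
            f.attrs["seed"] = run.seed


def read_bold(path) -> BoldRun:
    with h5py.File(path, "r") as f:
        return BoldRun(
            series=f["series"][()], fd=f["fd"][()], onsets=f["onsets"][()],
            roi_names=[n.decode() for n in f["roi_names"][()]],
            tr=float(f.attrs["tr"]), frames_on=int(f.attrs["frames_on"]),
            frames_off=int(f.attrs["frames_off"]),
            stim_group=str(f.attrs["stim_group"]), run_id=str(f.attrs["run_id"]),
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None)


# ---------------------------------------------------------------------------
# config and provenance
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def require_keys(cfg: dict, schema: dict, context: str = "config") -> None:
    """Validate presence and type of required keys; errors name the key."""
    for key, typ in schema.items():
        if key not in cfg:
            raise ValueError(f"{context}: missing key {key!r} (expected {typ.__name__})")
        if not isinstance(cfg[key], typ):
            raise ValueError(
                f"{context}: key {key!r} has type {type(cfg[key]).__name__}, "
                f"expected {typ.__name__}")


def write_provenance(path, seed: Optional[int] = None,
                     config: Optional[dict] = None, **extra) -> None:
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str) if config else ""
    rec = dict(version=__version__, seed=seed,
               config_sha256=hashlib.sha256(blob.encode()).hexdigest(),
               **extra)
    with open(path, "w") as f:
        json.dump(rec, f, indent=2, default=str)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
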