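"""Serialization: trial tables (CSV), LFP epochs (HDF5 + JSON sidecar),
behavioral fits and reports (JSON).

All tables are UTF-8 CSV with a fixed column order and fixed float
formatting ("%.10g"), so identical runs produce byte-identical files.
Missing values are written as empty fields.  The column dictionary ships in
docs/data_dictionary.md.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .spectral import LFPEpochSet

__all__ = [
    "write_trials", "read_trials",
    "write_epochs", "read_epochs",
    "write_fits", "read_fits",
    "write_json", "read_json",
]

FLOAT_FMT = "%.10g"


def write_trials(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    return path


def read_trials(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_epochs(epochs: LFPEpochSet, path) -> Path:
    """Write an epoch set as HDF5 (chunked by trial) plus a JSON sidecar
    with sampling metadata, channel regions and any ground truth."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data,
                         chunks=(1, epochs.data.shape[1], epochs.data.shape[2]))
        f.create_dataset("trial_ids", data=np.asarray(epochs.trial_ids, dtype=np.int64))
    sidecar = {
        "fs": float(epochs.fs),
        "t0": float(epochs.t0),
        "channels": list(epochs.channels),
        "regions": dict(epochs.regions),
        "participant": epochs.participant,
        "meta": _jsonable(epochs.meta),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def read_epochs(path) -> LFPEpochSet:
    path = Path(path)
    side = json.loads(path.with_suffix(".json").read_text())
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        trial_ids = f["trial_ids"][()]
    return LFPEpochSet(
        data=data, fs=side["fs"], t0=side["t0"],
        channels=list(side["channels"]), regions=dict(side["regions"]),
        trial_ids=trial_ids, participant=side.get("participant", "?"),
        meta=side.get("meta", {}),
    )


def write_fits(fits, path) -> Path:
    """Serialize BehavioralFit records (one per participant x condition)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = {pid: fit.to_dict() for pid, fit in fits.items()}
    path.write_text(json.dumps(records, indent=1, sort_keys=True))
    return path


def read_fits(path) -> dict:
    from .behavior import BehavioralFit
    raw = json.loads(Path(path).read_text())
    out = {}
    for pid, d in raw.items():
        d = dict(d)
        d["at_bound"] = tuple(d.get("at_bound", ()))
        out[pid] = BehavioralFit(**d)
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(obj), indent=1, sort_keys=True))
    return path


def read_json(path):
    return json.loads(Path(path).read_text())
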