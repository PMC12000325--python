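"""Container I/O: HDF5 trial arrays with JSON sidecars, TSV spike tables.

The trial container is an HDF5 file holding the raw array plus a JSON
sidecar (``<path>.json``) carrying everything human-auditable: sampling
rate, epoch, onset index, labels, generator configuration and planted
ground truth. Unknown sidecar keys are preserved verbatim on round-trip.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .containers import LabelSet, SpikeTrainSet, TrialSet

__all__ = [
    "SCHEMA_VERSION",
    "SchemaError",
    "write_trialset",
    "read_trialset",
    "write_spikes",
    "read_spikes",
    "load_config",
]

SCHEMA_VERSION = "phaseopp-container-1"


class SchemaError(RuntimeError):
    """Container schema version mismatch or unreadable file."""


def write_trialset(
    path: str | Path, trials: TrialSet, labels: LabelSet | None = None
) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=trials.data)
        f.attrs["schema"] = SCHEMA_VERSION
        f.attrs["fs"] = trials.fs
        f.attrs["t0_index"] = trials.t0_index
    sidecar = {
        "schema": SCHEMA_VERSION,
        "fs": trials.fs,
        "t0_index": trials.t0_index,
        "channel_ids": list(trials.channel_ids),
        "trial_ids": [int(t) for t in trials.trial_ids],
        "meta": trials.meta,
    }
    if labels is not None:
        sidecar["labels"] = labels.labels.tolist()
        if labels.ratings is not None:
            sidecar["ratings"] = labels.ratings.tolist()
        if labels.delays is not None:
            sidecar["delays"] = labels.delays.tolist()
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1)
    )
    return path


def read_trialset(path: str | Path) -> tuple[TrialSet, LabelSet | None]:
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            if f.attrs.get("schema") != SCHEMA_VERSION:
                raise SchemaError(
                    f"container schema {f.attrs.get('schema')!r} != {SCHEMA_VERSION!r}"
                )
            data = f["data"][...]
            fs = float(f.attrs["fs"])
            t0_index = int(f.attrs["t0_index"])
    except OSError as exc:
        raise SchemaError(f"unreadable container {path}: {exc}") from exc
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta, channel_ids, trial_ids, labels = {}, None, None, None
    if sidecar_path.exists():
        side = json.loads(sidecar_path.read_text())
        meta = side.get("meta", {})
        channel_ids = side.get("channel_ids")
        trial_ids = side.get("trial_ids")
        if "labels" in side:
            labels = LabelSet(
                labels=np.asarray(side["labels"], dtype=int),
                ratings=np.asarray(side["ratings"], float)
                if "ratings" in side
                else None,
                delays=np.asarray(side["delays"], float)
                if "delays" in side
                else None,
            )
    trials = TrialSet(
        data=data,
        fs=fs,
        t0_index=t0_index,
        channel_ids=channel_ids,
        trial_ids=trial_ids,
        meta=meta,
    )
    return trials, labels


def write_spikes(path: str | Path, spikes: SpikeTrainSet) -> Path:
    path = Path(path)
    spikes.events.to_csv(
        path, sep="\t", index=False, float_format="%.9g",
        columns=["unit", "trial", "time_s"],
    )
    return path


def read_spikes(path: str | Path) -> SpikeTrainSet:
    events = pd.read_csv(path, sep="\t")
    return SpikeTrainSet(events=events)


def load_config(path: str | Path) -> dict:
    """YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".json"}:
        return json.loads(text)
    return yaml.safe_load(text)
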