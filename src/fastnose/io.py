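"""Readers and writers: HDF5 recordings, CSV fixtures, TSV feature tables,
YAML protocols/panels and JSON reports."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import h5py
import numpy as np
import pandas as pd
import yaml

from .panel import OdorantPanel
from .protocol import Trial, trial_from_record, trial_to_record
from .sensor import Recording

SCHEMA_VERSION = 1
_CHANNELS = ("gas", "temp", "temp_target", "vdac", "vsense", "conc", "pid")


class SchemaError(IOError):
    """Raised on missing channels or schema-version mismatch."""


def write_recording(recording: Recording, path) -> None:
    """Lossless HDF5 serialization of all channels plus JSON metadata."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["fs"] = recording.fs
        f.attrs["odorants"] = json.dumps(list(recording.odorants))
        f.attrs["meta"] = json.dumps(recording.meta)
        f.create_dataset("time", data=recording.time)
        for name in _CHANNELS:
            f.create_dataset(name, data=getattr(recording, name))


def read_recording(path) -> Recording:
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise SchemaError(f"schema version mismatch: {version} != {SCHEMA_VERSION}")
        missing = [c for c in ("time",) + _CHANNELS if c not in f]
        if missing:
            raise SchemaError(f"missing channel(s): {missing}")
        data = {name: f[name][...] for name in _CHANNELS}
        return Recording(fs=int(f.attrs["fs"]), time=f["time"][...],
                         odorants=tuple(json.loads(f.attrs["odorants"])),
                         meta=json.loads(f.attrs["meta"]), **data)


def export_recording_csv(recording: Recording, path) -> None:
    """Flat CSV export for small fixtures (one column per channel row)."""
    cols = {"time": recording.time, "pid": recording.pid}
    for s in range(recording.n_sensors):
        cols[f"gas_{s}"] = recording.gas[s]
        cols[f"temp_{s}"] = recording.temp[s]
        cols[f"temp_target_{s}"] = recording.temp_target[s]
        cols[f"vdac_{s}"] = recording.vdac[s]
        cols[f"vsense_{s}"] = recording.vsense[s]
    for k, name in enumerate(recording.odorants):
        cols[f"conc_{name}"] = recording.conc[k]
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"# fastnose recording schema_version={SCHEMA_VERSION} "
                 f"fs={recording.fs} meta={json.dumps(recording.meta)}\n")
        df.to_csv(fh, index=False)


def import_recording_csv(path) -> Recording:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# fastnose recording"):
            raise SchemaError("not a fastnose CSV recording")
        meta = json.loads(header.split("meta=", 1)[1])
        fs = int(header.split("fs=")[1].split()[0])
        df = pd.read_csv(fh)
    n_sensors = len([c for c in df.columns if c.startswith("gas_")])
    odorants = tuple(c[len("conc_"):] for c in df.columns
                     if c.startswith("conc_"))
    stack = lambda prefix: np.stack(
        [df[f"{prefix}_{s}"].to_numpy() for s in range(n_sensors)])
    return Recording(fs=fs, time=df["time"].to_numpy(), gas=stack("gas"),
                     temp=stack("temp"), temp_target=stack("temp_target"),
                     vdac=stack("vdac"), vsense=stack("vsense"),
                     conc=np.stack([df[f"conc_{n}"].to_numpy() for n in odorants])
                     if odorants else np.zeros((0, len(df))),
                     pid=df["pid"].to_numpy(), odorants=odorants, meta=meta)


def write_features_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_features_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_protocol_yaml(trials, path) -> None:
    doc = {"schema_version": SCHEMA_VERSION,
           "trials": [trial_to_record(t) for t in trials]}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_protocol_yaml(path) -> list:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError("protocol schema version mismatch")
    return [trial_from_record(r) for r in doc["trials"]]


def write_panel_yaml(panel: OdorantPanel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"schema_version": SCHEMA_VERSION,
                        "odorants": panel.to_records()}, fh, sort_keys=False)


def read_panel_yaml(path) -> OdorantPanel:
    return OdorantPanel.from_yaml(path)


@dataclass
class RunConfig:
    """Top-level pipeline run description (round-trips losslessly through
    YAML)."""

    tasks: list = field(default_factory=lambda: ["static_odor_knn"])
    seed: int = 0
    scale: float = 1.0
    panel_path: str | None = None
    output_dir: str = "."
    log_level: str = "INFO"
    schema_version: int = SCHEMA_VERSION


def write_run_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


def read_run_config(path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError("run config schema version mismatch")
    return RunConfig(**doc)


def write_report_json(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj
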