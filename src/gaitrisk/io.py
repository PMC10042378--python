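"""Serialization: HDF5 containers for arrays, JSON for models and
manifests, CSV for tidy metric tables.

Every container carries a ``schema`` attribute; loading a container with an
unknown schema raises :class:`~gaitrisk.exceptions.SchemaError` rather than
silently misreading it.  CSV exports use 17 significant digits so round-trips
preserve doubles exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from typing import List, Optional

import h5py
import numpy as np
import pandas as pd

from .chain import AbsorbingChain
from .exceptions import SchemaError
from .metrics import METRIC_NAMES, MetricVector, NormalizationRecord
from .walker import DeterministicMesh, StepSequence, WalkerConfig

__all__ = [
    "save_mesh", "load_mesh",
    "save_chain", "load_chain",
    "save_trials", "load_trials",
    "metric_table_to_csv", "metric_table_from_csv",
    "save_normalization", "load_normalization",
    "RunManifest",
]

_MESH_SCHEMA = "gaitrisk.mesh/1"
_CHAIN_SCHEMA = "gaitrisk.chain/1"
_TRIALS_SCHEMA = "gaitrisk.trials/1"
_CSV_FLOAT = "%.17g"


def _check_schema(obj, expected: str) -> None:
    found = obj.attrs.get("schema")
    if found != expected:
        raise SchemaError(
            f"expected schema {expected!r}, found {found!r}; "
            "no migration path is defined")


def save_mesh(mesh: DeterministicMesh, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = _MESH_SCHEMA
        f.attrs["config"] = mesh.config.to_yaml()
        f.create_dataset("states", data=mesh.states)
        f.create_dataset("transitions", data=mesh.transitions)
        f.create_dataset("perturbation_grid", data=mesh.perturbation_grid)


def load_mesh(path) -> DeterministicMesh:
    with h5py.File(path, "r") as f:
        _check_schema(f, _MESH_SCHEMA)
        config = WalkerConfig.from_yaml(f.attrs["config"])
        return DeterministicMesh(
            config=config,
            states=f["states"][...],
            transitions=f["transitions"][...],
            perturbation_grid=f["perturbation_grid"][...])


def save_chain(chain: AbsorbingChain, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = _CHAIN_SCHEMA
        if chain.noise_sd is not None:
            f.attrs["noise_sd"] = chain.noise_sd
        if chain.mesh is not None:
            f.attrs["config"] = chain.mesh.config.to_yaml()
        f.create_dataset("Q", data=chain.Q)
        f.create_dataset("R", data=chain.R)
        f.create_dataset("state_labels", data=chain.state_labels)


def load_chain(path, mesh: Optional[DeterministicMesh] = None
               ) -> AbsorbingChain:
    with h5py.File(path, "r") as f:
        _check_schema(f, _CHAIN_SCHEMA)
        return AbsorbingChain(
            Q=f["Q"][...], R=f["R"][...],
            state_labels=f["state_labels"][...],
            mesh=mesh,
            noise_sd=float(f.attrs["noise_sd"])
            if "noise_sd" in f.attrs else None)


def save_trials(trials: List[StepSequence], path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = _TRIALS_SCHEMA
        f.attrs["n_trials"] = len(trials)
        if trials:
            f.attrs["config"] = trials[0].config.to_yaml()
        for k, trial in enumerate(trials):
            grp = f.create_group(f"trial_{k:04d}")
            grp.create_dataset("x0", data=trial.x0)
            grp.create_dataset("s", data=trial.s)
            grp.attrs["failed"] = bool(trial.failed)


def load_trials(path) -> List[StepSequence]:
    with h5py.File(path, "r") as f:
        _check_schema(f, _TRIALS_SCHEMA)
        n = int(f.attrs["n_trials"])
        config = WalkerConfig.from_yaml(f.attrs["config"]) if n else None
        out = []
        for k in range(n):
            grp = f[f"trial_{k:04d}"]
            out.append(StepSequence(
                config, grp["x0"][...], grp["s"][...],
                failed=bool(grp.attrs["failed"])))
        return out


def metric_table_to_csv(df: pd.DataFrame, path) -> None:
    """Tidy export: one row per condition, 49 named metric columns."""
    df.to_csv(path, float_format=_CSV_FLOAT, index_label="condition")


def metric_table_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="condition",
                     float_precision="round_trip")
    missing = [c for c in METRIC_NAMES if c not in df.columns]
    if missing:
        raise SchemaError(f"metric table lacks columns {missing[:3]}...")
    return df[METRIC_NAMES]


def save_normalization(record: NormalizationRecord, path) -> None:
    with open(path, "w") as fh:
        json.dump({"schema": "gaitrisk.normalization/1",
                   "metrics": list(record.center.index),
                   "center": [float(x) for x in record.center],
                   "scale": [float(x) for x in record.scale]}, fh, indent=1)


def load_normalization(path) -> NormalizationRecord:
    with open(path) as fh:
        d = json.load(fh)
    if d.get("schema") != "gaitrisk.normalization/1":
        raise SchemaError(f"unexpected schema {d.get('schema')!r}")
    return NormalizationRecord(
        pd.Series(d["center"], index=d["metrics"]),
        pd.Series(d["scale"], index=d["metrics"]))


@dataclass
class RunManifest:
    """Provenance record tying configs, seeds and outputs together."""

    config_hash: str
    seeds: dict
    files: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    created: float = field(default_factory=time.time)
    schema: str = "gaitrisk.manifest/1"

    @staticmethod
    def hash_config(config: WalkerConfig) -> str:
        return hashlib.sha256(config.to_yaml().encode()).hexdigest()

    def register(self, name: str, path) -> None:
        self.files[name] = str(path)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, default=str)

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("schema") != "gaitrisk.manifest/1":
            raise SchemaError(f"unexpected schema {d.get('schema')!r}")
        return cls(**d)
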