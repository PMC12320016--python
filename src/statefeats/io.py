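"""Epoch-container I/O, configuration files and run manifests.

The primary epoch store is a hierarchical HDF5 container: one group per
subject holding the epochs array, state labels, sampling rate and unit
names. A plain-text fallback (one CSV per subject in a directory) exists
for fully text-based workflows. YAML carries configuration; every CLI
invocation writes one JSON run manifest echoing config, seeds and paths.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .synth import STATES, CohortConfig, EpochedRecording

__all__ = [
    "read_epochs",
    "write_epochs",
    "read_feature_table",
    "load_config",
    "RunManifest",
]


@dataclass
class RunManifest:
    command: str
    config: dict
    seed: int | None
    inputs: list[str]
    outputs: list[str]
    timestamp: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def write_epochs(
    cohort: list[EpochedRecording], path: str | Path, format: str = "hier_container"
) -> None:
    path = Path(path)
    if format == "hier_container":
        with h5py.File(path, "w") as f:
            for rec in cohort:
                g = f.create_group(rec.subject_id)
                g.create_dataset("epochs", data=rec.epochs)
                g.create_dataset(
                    "state_labels",
                    data=np.array([s.encode() for s in rec.state_labels]),
                )
                g.attrs["fs"] = rec.fs
                g.attrs["unit_names"] = [u.encode() for u in rec.unit_names]
    elif format == "delimited_dir":
        path.mkdir(parents=True, exist_ok=True)
        for rec in cohort:
            n_ep, n_u, n_s = rec.epochs.shape
            rows = []
            for e in range(n_ep):
                for u in range(n_u):
                    rows.append(
                        [e, str(rec.state_labels[e]), rec.unit_names[u]]
                        + list(rec.epochs[e, u])
                    )
            cols = ["epoch", "state", "unit"] + [f"s{i}" for i in range(n_s)]
            df = pd.DataFrame(rows, columns=cols)
            df.insert(0, "fs", rec.fs)
            df.to_csv(path / f"{rec.subject_id}.csv", index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def _validation_error(subject: str, msg: str) -> ValueError:
    return ValueError(f"validation error in record {subject!r}: {msg}")


def read_epochs(
    path: str | Path,
    format: str = "hier_container",
    channel_subset: list[str] | None = None,
) -> list[EpochedRecording]:
    """Load and validate a cohort; optionally keep only named spatial units."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cohort: list[EpochedRecording] = []
    if format == "hier_container":
        with h5py.File(path, "r") as f:
            for sid in sorted(f.keys()):
                g = f[sid]
                labels = [b.decode() for b in g["state_labels"][()]]
                units = [
                    u.decode() if isinstance(u, bytes) else str(u)
                    for u in g.attrs["unit_names"]
                ]
                cohort.append(
                    _validated(sid, g["epochs"][()], labels, float(g.attrs["fs"]), units)
                )
    elif format == "delimited_dir":
        for csv in sorted(path.glob("*.csv")):
            df = pd.read_csv(csv)
            fs = float(df["fs"].iloc[0])
            units = list(pd.unique(df["unit"]))
            n_ep = int(df["epoch"].max()) + 1
            sample_cols = [c for c in df.columns if c.startswith("s") and c[1:].isdigit()]
            epochs = np.empty((n_ep, len(units), len(sample_cols)))
            labels = [""] * n_ep
            for _, row in df.iterrows():
                e, u = int(row["epoch"]), units.index(row["unit"])
                epochs[e, u] = row[sample_cols].to_numpy(dtype=float)
                labels[e] = str(row["state"])
            cohort.append(_validated(csv.stem, epochs, labels, fs, units))
    else:
        raise ValueError(f"unknown format {format!r}")

    if channel_subset is not None:
        cohort = [_subset(rec, channel_subset) for rec in cohort]
    return cohort


def _validated(sid, epochs, labels, fs, units) -> EpochedRecording:
    unknown = set(labels) - set(STATES)
    if unknown:
        raise _validation_error(sid, f"unknown state label(s) {sorted(unknown)}")
    try:
        return EpochedRecording(sid, np.asarray(epochs), np.asarray(labels), fs, units)
    except ValueError as e:
        raise _validation_error(sid, str(e)) from e


def _subset(rec: EpochedRecording, names: list[str]) -> EpochedRecording:
    missing = [n for n in names if n not in rec.unit_names]
    if missing:
        raise _validation_error(rec.subject_id, f"unknown spatial units {missing}")
    idx = [rec.unit_names.index(n) for n in names]
    return EpochedRecording(
        rec.subject_id, rec.epochs[:, idx, :], rec.state_labels, rec.fs, list(names)
    )


def load_config(path: str | Path) -> CohortConfig:
    """Cohort configuration from a YAML file; master_seed is mandatory."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "master_seed" not in raw:
        raise ValueError("configuration must declare master_seed")
    allowed = {f for f in CohortConfig.__dataclass_fields__}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    return CohortConfig(**raw)


def read_feature_table(path: str | Path):
    """Rebuild a FeatureTable from the long/wide CSV written by the pipeline."""
    from .classify import FeatureTable

    df = pd.read_csv(path)
    meta_cols = ["subject", "state", "epoch_order"]
    feat_cols = [c for c in df.columns if c not in meta_cols]
    column_meta = [tuple(c.split("__", 1)) for c in feat_cols]
    return FeatureTable(
        X=df[feat_cols].to_numpy(dtype=float),
        y=df["state"].to_numpy(),
        subject=df["subject"].to_numpy(),
        epoch_order=df["epoch_order"].to_numpy(),
        column_meta=column_meta,
    )
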