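"""Localization-table and configuration I/O.

HDF5 files follow the common SMLM convention: a single structured-array
dataset named ``locs`` with named columns, accompanied by a YAML sidecar
(same path with extension ``.yaml``) carrying the pixel size and acquisition
metadata.  CSV mirrors the columns for inspection.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

MANDATORY_COLUMNS = ["frame", "x", "y", "photons", "sx", "sy", "bg"]

__all__ = ["save_localizations", "load_localizations", "MANDATORY_COLUMNS"]


def _validate(table: pd.DataFrame) -> None:
    for col in MANDATORY_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"localization table is missing mandatory column {col!r}")


def save_localizations(path, table: pd.DataFrame, metadata: dict | None = None) -> None:
    """Write a localization table to HDF5 (``.hdf5``/``.h5``) or CSV.

    HDF5 output stores one structured dataset ``locs``; metadata (pixel
    size, acquisition parameters) goes into a YAML sidecar next to the file.
    """
    _validate(table)
    path = Path(path)
    if path.suffix in (".hdf5", ".h5"):
        rec = table.to_records(index=False)
        with h5py.File(path, "w") as f:
            f.create_dataset("locs", data=rec)
        if metadata is not None:
            sidecar = path.with_suffix(".yaml")
            with open(sidecar, "w") as f:
                yaml.safe_dump(metadata, f)
    elif path.suffix == ".csv":
        table.to_csv(path, index=False)
        if metadata is not None:
            with open(path.with_suffix(".yaml"), "w") as f:
                yaml.safe_dump(metadata, f)
    else:
        raise ValueError(f"unsupported localization format: {path.suffix!r}")


def load_localizations(path) -> tuple[pd.DataFrame, dict | None]:
    """Read a localization table (HDF5 or CSV) plus its YAML sidecar if present."""
    path = Path(path)
    if path.suffix in (".hdf5", ".h5"):
        with h5py.File(path, "r") as f:
            if "locs" not in f:
                raise ValueError(f"{path} has no 'locs' dataset")
            table = pd.DataFrame.from_records(f["locs"][()])
    elif path.suffix == ".csv":
        table = pd.read_csv(path)
    else:
        raise ValueError(f"unsupported localization format: {path.suffix!r}")
    _validate(table)
    metadata = None
    sidecar = path.with_suffix(".yaml")
    if sidecar.exists():
        with open(sidecar) as f:
            metadata = yaml.safe_load(f)
    return table, metadata
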