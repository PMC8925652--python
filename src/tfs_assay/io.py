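"""Container round-tripping: HDF5 epoch files, trial-log TSVs, cohort CSVs.

The epoch container is a plain HDF5 file:

* ``/data``  — trials × channels × time, float64 (μV)
* ``/mask``  — per-trial rejection flags
* ``/labels`` — per-trial condition labels
* a JSON-encoded ``meta`` attribute with rate, window, channel names,
  event code and schema version.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from tfs_assay.eeg import EpochArray
from tfs_assay.staircase import StaircaseRun

SCHEMA_VERSION = 1

__all__ = ["save_epochs", "load_epochs", "staircase_log_tsv", "read_staircase_log"]


def save_epochs(epochs: EpochArray, path) -> None:
    """Write an :class:`EpochArray` to the HDF5 epoch container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("mask", data=epochs.rejected)
        labels = np.asarray(epochs.labels)
        if labels.dtype.kind in "UO":
            labels = labels.astype(h5py.string_dtype())
        f.create_dataset("labels", data=labels)
        f.attrs["meta"] = json.dumps({
            "schema_version": SCHEMA_VERSION,
            "rate": epochs.rate,
            "tmin": epochs.tmin,
            "ch_names": epochs.ch_names,
            "event_code": epochs.event_code,
        })


def load_epochs(path) -> EpochArray:
    """Read the HDF5 epoch container back; exact round-trip of data/mask/labels."""
    try:
        with h5py.File(path, "r") as f:
            if "data" not in f or "meta" not in f.attrs:
                raise ValueError(f"not a valid epoch container: {path}")
            meta = json.loads(f.attrs["meta"])
            if meta.get("schema_version") != SCHEMA_VERSION:
                raise ValueError(
                    f"epoch container schema {meta.get('schema_version')} "
                    f"!= supported {SCHEMA_VERSION}")
            labels = f["labels"][()]
            if labels.dtype.kind in "SO":
                labels = np.array([v.decode() if isinstance(v, bytes) else v for v in labels])
            return EpochArray(f["data"][()], meta["rate"], meta["tmin"],
                              list(meta["ch_names"]), event_code=meta["event_code"],
                              labels=labels, rejected=f["mask"][()])
    except OSError as err:
        raise ValueError(f"corrupt or unreadable epoch container: {path}") from err


def staircase_log_tsv(runs: list[StaircaseRun], block_offset: int = 0) -> str:
    """Trial logs of one or more blocks as TSV text."""
    lines = ["block\ttrial\tstimulus_db\tcorrect\tis_catch"]
    for b, run in enumerate(runs, start=block_offset):
        for i, (x, ok, catch) in enumerate(run.trials):
            lines.append(f"{b}\t{i}\t{x:.4f}\t{int(ok)}\t{int(catch)}")
    return "\n".join(lines) + "\n"


def read_staircase_log(text_or_path) -> pd.DataFrame:
    """Parse a trial-log TSV into a DataFrame (block, trial, stimulus_db, …)."""
    import io as _io

    src = text_or_path
    if isinstance(src, str) and "\t" in src:
        src = _io.StringIO(src)
    return pd.read_csv(src, sep="\t")
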