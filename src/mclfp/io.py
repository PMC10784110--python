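"""Reading and writing recordings, source signals, PSDs and band tables.

Recordings round-trip losslessly through HDF5 (dataset ``samples``, key
metadata as attributes, the full config tree as a JSON attribute) and
through two-column CSV (``time_s,value`` header; the sampling rate is
recovered from the time column).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .device import Recording
from .signals import SourceSignal
from .spectral import LogPSD

__all__ = [
    "read_recording",
    "write_recording",
    "write_source_csv",
    "write_logpsd_csv",
    "read_logpsd_csv",
    "write_band_table",
]

_SCALAR_ATTRS = ("seed", "stim_amplitude", "amp_model")


class FormatError(ValueError):
    """Raised on malformed or metadata-deficient input files."""


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in (".h5", ".hdf5"):
        return "hdf5"
    if suffix in (".csv", ".txt"):
        return "csv"
    raise FormatError(f"cannot infer format from {path!r}; pass format explicitly")


def write_recording(rec: Recording, path: str | Path, fmt: str | None = None) -> None:
    fmt = _infer_format(path, fmt)
    if fmt == "hdf5":
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("samples", data=rec.samples)
            ds.attrs["fs"] = rec.fs
            ds.attrs["meta_json"] = json.dumps(rec.meta)
            for key in _SCALAR_ATTRS:
                if key in rec.meta:
                    ds.attrs[key] = rec.meta[key]
            lead = rec.meta.get("lead", {})
            for key in ("Z1", "Z3"):
                if key in lead:
                    ds.attrs[key] = lead[key]
    elif fmt == "csv":
        df = pd.DataFrame({"time_s": rec.times, "value": rec.samples})
        df.to_csv(path, index=False)
    else:
        raise FormatError(f"unknown format {fmt!r}")


def read_recording(path: str | Path, fmt: str | None = None) -> Recording:
    """Load a recording; CSV infers fs from the time column (raises on a
    non-uniform grid), HDF5 restores the full metadata tree."""
    fmt = _infer_format(path, fmt)
    if fmt == "hdf5":
        with h5py.File(path, "r") as fh:
            if "samples" not in fh:
                raise FormatError(f"{path}: no 'samples' dataset")
            ds = fh["samples"]
            if "fs" not in ds.attrs:
                raise FormatError(f"{path}: missing required 'fs' attribute")
            meta = json.loads(ds.attrs.get("meta_json", "{}"))
            return Recording(ds[()], float(ds.attrs["fs"]), meta)
    if fmt == "csv":
        return _read_csv_recording(path)
    raise FormatError(f"unknown format {fmt!r}")


def _read_csv_recording(path: str | Path) -> Recording:
    with open(path) as fh:
        header = fh.readline().strip()
        if header.split(",")[:2] != ["time_s", "value"]:
            raise FormatError(f"{path}:1: expected header 'time_s,value', got {header!r}")
        times, values = [], []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            try:
                times.append(float(parts[0]))
                values.append(float(parts[1]))
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed row {line!r}") from exc
    if len(times) < 2:
        raise FormatError(f"{path}: need at least two samples to infer fs")
    dt = np.diff(times)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise FormatError(f"{path}: non-uniform time grid")
    return Recording(np.asarray(values), 1.0 / dt[0], meta={"source": str(path)})


def write_source_csv(sig: SourceSignal, path: str | Path) -> None:
    pd.DataFrame({"time_s": sig.times, "value": sig.samples}).to_csv(path, index=False)


def write_logpsd_csv(psd: LogPSD, path: str | Path) -> None:
    pd.DataFrame({"freq_hz": psd.freqs, "power_db": psd.values}).to_csv(path, index=False)


def read_logpsd_csv(path: str | Path) -> LogPSD:
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["freq_hz", "power_db"]:
        raise FormatError(f"{path}: expected columns freq_hz,power_db")
    return LogPSD(df["freq_hz"].to_numpy(), df["power_db"].to_numpy(), {"source": str(path)})


def write_band_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
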