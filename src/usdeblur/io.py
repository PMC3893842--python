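"""Delimited-text and HDF5 input/output for lines, frames and kernels."""

from __future__ import annotations

from dataclasses import asdict
from typing import Optional

import h5py
import numpy as np

from .synthetic import SimConfig

__all__ = ["save_simulation_h5", "load_h5", "read_signal", "write_signal"]


def save_simulation_h5(path, rf, reflectivity=None, envelope_truth=None, psf=None,
                       cfg: Optional[SimConfig] = None) -> None:
    """Write a simulated line/frame with its ground truth and pulse."""
    with h5py.File(path, "w") as f:
        f.create_dataset("rf", data=np.asarray(rf, dtype=float))
        if reflectivity is not None:
            f.create_dataset("reflectivity", data=np.asarray(reflectivity, dtype=float))
        if envelope_truth is not None:
            f.create_dataset("envelope_truth", data=np.asarray(envelope_truth, dtype=float))
        if psf is not None:
            f.create_dataset("psf", data=np.asarray(psf, dtype=float))
        if cfg is not None:
            for key, val in asdict(cfg).items():
                if val is not None:
                    f.attrs[key] = val


def load_h5(path) -> dict:
    """Read every dataset and attribute of an HDF5 file into a flat dict."""
    out = {}
    with h5py.File(path, "r") as f:
        for name in f:
            out[name] = f[name][()]
        out["attrs"] = dict(f.attrs)
    return out


def read_signal(path) -> np.ndarray:
    """Load a 1-D or 2-D signal from CSV/TSV/TXT or HDF5 ('rf' or 'frame' dataset)."""
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "r") as f:
            for name in ("rf", "frame", "envelope", "data"):
                if name in f:
                    return f[name][()].astype(float)
            raise KeyError(f"no recognised dataset in {path}")
    return np.atleast_1d(np.loadtxt(path, delimiter="," if path.endswith(".csv") else None))


def write_signal(path, arr) -> None:
    """Save an array as CSV (text) or HDF5 ('data' dataset) by extension."""
    path = str(path)
    arr = np.asarray(arr, dtype=float)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=arr)
    else:
        np.savetxt(path, arr, delimiter=",")
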