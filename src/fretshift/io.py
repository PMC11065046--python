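"""Tabular and HDF5 output: burst tables, summary JSON, photon export."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .experiment import BURST_COLUMNS, ExperimentResult

__all__ = [
    "write_burst_table",
    "read_burst_table",
    "write_summary_json",
    "export_photon_hdf5",
    "table_digest",
]

_HEADER = (
    "# fretshift burst table\n"
    "# units: lengths A, times ns, rates 1/ns; tau_norm = tau_D(A)/tau_D(0)\n"
)


def write_burst_table(result: ExperimentResult | pd.DataFrame,
                      path: str | Path) -> Path:
    """Write the burst table as TSV (full float precision, stable row order)."""
    df = getattr(result, "bursts", result)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_HEADER)
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")
    return path


def read_burst_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    missing = [c for c in BURST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"burst table missing columns: {missing}")
    return df


def table_digest(df: pd.DataFrame) -> str:
    """SHA-256 of the canonical TSV serialization (fixture digests)."""
    return hashlib.sha256(
        df.to_csv(sep="\t", index=False, float_format="%.17g").encode()
    ).hexdigest()


def write_summary_json(summary: dict, path: str | Path) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(summary, indent=2, default=default) + "\n")
    return path


def export_photon_hdf5(result: ExperimentResult, path: str | Path,
                       timestamp_unit: float = 1e-9) -> Path:
    """Minimal Photon-HDF5-style export of the per-photon event table.

    Requires the experiment to have been run with ``store_photons=True``.
    Field naming follows the Photon-HDF5 convention: photon_data/timestamps
    (integer clock ticks), photon_data/detectors (0 donor, 1 acceptor).
    """
    import h5py

    if result.photons is None:
        raise ValueError("no photon table; run the experiment with store_photons=True")
    path = Path(path)
    ph = result.photons
    timestamps = np.round(ph["delay_ns"].to_numpy() * 1e-9
                          / timestamp_unit).astype(np.int64)
    detectors = (ph["channel"] == "acceptor").to_numpy().astype(np.uint8)
    with h5py.File(path, "w") as f:
        g = f.create_group("photon_data")
        g.create_dataset("timestamps", data=timestamps)
        g["timestamps"].attrs["timestamps_unit"] = timestamp_unit
        g.create_dataset("detectors", data=detectors)
        g.create_dataset("burst_ids", data=ph["burst_id"].to_numpy(np.int64))
        setup = f.create_group("setup")
        setup.attrs["num_spectral_ch"] = 2
        f.attrs["acquisition_duration"] = float(result.config.total_duration)
        f.attrs["identity"] = "fretshift simulation"
        f.attrs["seed"] = result.seed
    return path
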