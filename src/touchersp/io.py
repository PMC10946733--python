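"""TSV fixture and HDF5 container I/O.

All on-disk formats are plain text (TSV with a JSON sidecar where metadata is
needed); epochs and band maps can additionally be persisted to an HDF5
container for reuse between sessions.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from touchersp.kinetics import SENSOR_COLUMNS, SixAxisRecording
from touchersp.preprocess import EegEpochs, EegRecording

FLOAT_FMT = "%.6g"


def write_sensor_tsv(path: str | Path, data: pd.DataFrame) -> None:
    """Six-axis sensor TSV: t_ms, Fx_N..Mz_Nm.  A header comment documents the
    sign convention shared with the kinetics stage."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# six-axis sensor; compression gives Fz < 0; contact plane at z = -h\n")
        data.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


def read_sensor_tsv(path: str | Path, fs: float, events: pd.DataFrame) -> SixAxisRecording:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in SENSOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing sensor columns {missing}")
    return SixAxisRecording(df, fs, events)


def write_eeg_tsv(path: str | Path, rec: EegRecording) -> None:
    """EEG fixture: one row per sample, one column per channel (uV); sampling
    rate and units in a ``.json`` sidecar."""
    path = Path(path)
    df = pd.DataFrame(rec.data.T, columns=rec.ch_names)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    sidecar = {"fs_hz": rec.fs, "units": "uV", "n_channels": len(rec.ch_names)}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_eeg_tsv(path: str | Path, montage: pd.DataFrame | None = None) -> EegRecording:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    df = pd.read_csv(path, sep="\t")
    return EegRecording(df.to_numpy().T, float(sidecar["fs_hz"]), list(df.columns), montage)


def write_montage_tsv(path: str | Path, montage: pd.DataFrame) -> None:
    montage.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_montage_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("label", "x_m", "y_m", "z_m"):
        if col not in df.columns:
            raise ValueError(f"{path}: montage missing column {col!r}")
    return df


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_epochs(path: str | Path, ep: EegEpochs) -> None:
    """Persist epochs to HDF5 with labels/time axis/provenance in attributes."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=ep.data, compression="gzip", compression_opts=1)
        fh.create_dataset("t_ms", data=ep.t_ms)
        fh.attrs["fs"] = ep.fs
        fh.attrs["subject"] = ep.subject
        fh.attrs["ch_names"] = json.dumps(ep.ch_names)
        fh.attrs["trials"] = ep.trials.to_json(orient="split")
        fh.attrs["provenance"] = json.dumps(ep.provenance)


def load_epochs(path: str | Path) -> EegEpochs:
    import io as _io

    with h5py.File(path, "r") as fh:
        trials = pd.read_json(_io.StringIO(fh.attrs["trials"]), orient="split")
        return EegEpochs(
            data=fh["data"][()],
            t_ms=fh["t_ms"][()],
            fs=float(fh.attrs["fs"]),
            trials=trials,
            ch_names=json.loads(fh.attrs["ch_names"]),
            subject=str(fh.attrs["subject"]),
            provenance=json.loads(fh.attrs["provenance"]),
        )
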