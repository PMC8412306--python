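"""Readers and writers for the formats the toolkit consumes and emits.

Continuous recordings arrive either as HDF5/MAT containers (both legacy MAT
and HDF5-based MAT v7.3 are handled, with configurable dataset keys since
container layouts vary between labs) or as plain numeric matrices.  Event
and electrode tables follow the BIDS-iEEG tab-separated conventions
(``_events.tsv`` with onset / duration / electrical_stimulation_site;
``_electrodes.tsv`` with name / x / y / z).  Epoched trial matrices
round-trip through a small HDF5 layout with datasets ``V`` (T x K),
``time``, ``labels`` and ``fs``.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .epoching import EventTable, TrialMatrix

__all__ = [
    "read_events_tsv",
    "write_events_tsv",
    "read_electrodes_tsv",
    "write_trials_hdf5",
    "read_trials_hdf5",
    "read_raw",
    "read_matrix",
]


def read_events_tsv(path) -> EventTable:
    """BIDS-iEEG style events table: onset (s) + electrical_stimulation_site."""
    df = pd.read_csv(path, sep="\t")
    if "onset" not in df.columns:
        raise ValueError(f"{path}: events table needs an 'onset' column")
    for cand in ("electrical_stimulation_site", "trial_type", "label"):
        if cand in df.columns:
            labels = df[cand].to_numpy()
            break
    else:
        raise ValueError(
            f"{path}: no stimulation-site column "
            "(electrical_stimulation_site / trial_type / label)"
        )
    return EventTable(onset=df["onset"].to_numpy(dtype=float), label=labels)


def write_events_tsv(path, events: EventTable) -> None:
    df = pd.DataFrame(
        {
            "onset": events.onset,
            "duration": np.zeros(events.n_events),
            "electrical_stimulation_site": events.label,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_electrodes_tsv(path) -> pd.DataFrame:
    """BIDS-iEEG electrodes table: name, x, y, z coordinates."""
    df = pd.read_csv(path, sep="\t")
    missing = {"name", "x", "y", "z"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: electrodes table missing columns {sorted(missing)}")
    return df


def write_trials_hdf5(path, trials: TrialMatrix) -> None:
    labels = np.asarray(trials.labels).astype("S")
    with h5py.File(path, "w") as f:
        f.create_dataset("V", data=trials.values)
        f.create_dataset("time", data=trials.time)
        f.create_dataset("labels", data=labels)
        f.create_dataset("fs", data=float(trials.fs))


def read_trials_hdf5(path) -> TrialMatrix:
    with h5py.File(path, "r") as f:
        for key in ("V", "time", "labels", "fs"):
            if key not in f:
                raise ValueError(f"{path}: missing dataset {key!r}")
        values = f["V"][()]
        time = f["time"][()]
        labels = np.array([s.decode() for s in f["labels"][()]])
        fs = float(f["fs"][()])
    return TrialMatrix(values=values, time=time, fs=fs, labels=labels)


def _decode_channel_names(obj) -> list[str]:
    out = []
    for c in np.ravel(np.asarray(obj)):
        if isinstance(c, bytes):
            out.append(c.decode())
        else:
            out.append(str(np.ravel(c)[0]) if isinstance(c, np.ndarray) else str(c))
    return out


def read_raw(
    path,
    channel: str | int | None = None,
    data_key: str = "data",
    fs_key: str = "fs",
    channel_key: str = "channels",
) -> tuple[np.ndarray, float]:
    """Continuous trace + sampling rate from an HDF5 or MAT container.

    ``data`` may be a 1-D trace or a channels x samples matrix; in the
    latter case ``channel`` selects by name (via the channel-name dataset)
    or integer index.  Unknown channels raise an error that lists what is
    available.  Keys are configurable because MAT container layouts differ.
    """
    path = Path(path)
    arrays = {}
    try:
        with h5py.File(path, "r") as f:  # HDF5 or MAT v7.3
            for key in (data_key, fs_key, channel_key):
                if key in f:
                    arrays[key] = f[key][()]
    except OSError:
        from scipy.io import loadmat  # legacy MAT

        mat = loadmat(path, squeeze_me=False)
        for key in (data_key, fs_key, channel_key):
            if key in mat:
                arrays[key] = mat[key]
    if data_key not in arrays or fs_key not in arrays:
        raise ValueError(
            f"{path}: expected datasets {data_key!r} and {fs_key!r}; "
            f"found {sorted(arrays)}"
        )
    data = np.asarray(arrays[data_key], dtype=float)
    fs = float(np.ravel(arrays[fs_key])[0])
    data = np.squeeze(data)
    if data.ndim == 1:
        return data, fs
    if data.ndim != 2:
        raise ValueError(f"{path}: data must be 1-D or 2-D, got shape {data.shape}")
    # orient channels x samples (samples is the long axis)
    if data.shape[0] > data.shape[1]:
        data = data.T
    names = (
        _decode_channel_names(arrays[channel_key])
        if channel_key in arrays
        else [str(i) for i in range(data.shape[0])]
    )
    if channel is None:
        raise ValueError(
            f"{path}: multi-channel container; pick one of {names}"
        )
    if isinstance(channel, (int, np.integer)):
        idx = int(channel)
        if not 0 <= idx < data.shape[0]:
            raise ValueError(f"{path}: channel index {idx} out of range; available: {names}")
    else:
        if channel not in names:
            raise ValueError(
                f"{path}: channel {channel!r} not found; available: {names}"
            )
        idx = names.index(channel)
    return data[idx], fs


def read_matrix(path, delimiter: str = "\t") -> np.ndarray:
    """Plain numeric matrix from delimited text or an .npz/.npy file."""
    path = Path(path)
    if path.suffix == ".npy":
        return np.load(path)
    if path.suffix == ".npz":
        with np.load(path) as z:
            return z[list(z.keys())[0]]
    return np.loadtxt(path, delimiter=delimiter)
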