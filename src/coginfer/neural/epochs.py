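"""Epoch container: epochs x channels x time with per-epoch metadata."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EpochSet", "write_epochs_h5", "read_epochs_h5"]


@dataclass
class EpochSet:
    """Multichannel epochs locked to an event.

    data : (n_epochs, n_channels, n_times)
    times : seconds relative to the lock event, strictly increasing
    channels : frame with columns 'label', 'caudal' (rostro-caudal
        coordinate in [0, 1], 1 = most caudal) and optionally
        'hemisphere' (-1 left / +1 right / 0 midline)
    metadata : one row per epoch (regressors, condition, position,
        consistency, trial_id, outcome, response_side as applicable)
    """

    data: np.ndarray
    times: np.ndarray
    channels: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be epochs x channels x time")
        if len(self.metadata) != self.data.shape[0]:
            raise ValueError("metadata length must equal epoch count")
        if len(self.channels) != self.data.shape[1]:
            raise ValueError("channel table must match channel count")
        if len(self.times) != self.data.shape[2]:
            raise ValueError("time axis must match data")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time axis must be strictly increasing")

    @property
    def sfreq(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times)))

    def __len__(self) -> int:
        return self.data.shape[0]

    def select(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(self.data[mask], self.times, self.channels,
                        self.metadata.loc[mask].reset_index(drop=True))


def write_epochs_h5(path, epochs: EpochSet) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip")
        f.create_dataset("time", data=epochs.times)
        g = f.create_group("channels")
        g.create_dataset("label", data=np.asarray(epochs.channels["label"], dtype="S"))
        g.create_dataset("caudal", data=epochs.channels["caudal"].to_numpy(float))
        if "hemisphere" in epochs.channels:
            g.create_dataset("hemisphere", data=epochs.channels["hemisphere"].to_numpy(int))
        m = f.create_group("metadata")
        m.attrs["columns"] = list(epochs.metadata.columns)
        for col in epochs.metadata.columns:
            vals = epochs.metadata[col].to_numpy()
            if vals.dtype.kind in "OU":
                m.create_dataset(col, data=np.asarray(vals, dtype="S"))
            else:
                m.create_dataset(col, data=vals)


def read_epochs_h5(path) -> EpochSet:
    import h5py

    with h5py.File(path, "r") as f:
        data = f["data"][()]
        times = f["time"][()]
        ch = {"label": [s.decode() for s in f["channels/label"][()]],
              "caudal": f["channels/caudal"][()]}
        if "hemisphere" in f["channels"]:
            ch["hemisphere"] = f["channels/hemisphere"][()]
        meta = {}
        order = list(f["metadata"].attrs.get("columns", f["metadata"]))
        for col in order:
            vals = f["metadata"][col][()]
            if vals.dtype.kind == "S":
                vals = np.array([s.decode() for s in vals], dtype=object)
            meta[col] = vals
    return EpochSet(data, times, pd.DataFrame(ch), pd.DataFrame(meta))
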