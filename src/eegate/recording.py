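"""The multichannel time-series container shared by all signal stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

__all__ = ["Recording"]


@dataclass
class Recording:
    """Multichannel EEG time series.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` amplitudes in microvolts.
    fs
        Sampling rate in Hz.
    channel_names
        One label per row of ``data``.
    t0
        Start time of the first sample in seconds.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must equal number of data rows")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_names.index(name)]

    def with_data(self, data: np.ndarray) -> "Recording":
        """Copy of this recording with replaced sample matrix."""
        return replace(self, data=data)

    # -- persistence ------------------------------------------------------
    def to_hdf5(self, path) -> None:
        """Write to HDF5: datasets ``/data`` (µV), ``/fs``, ``/channels``, ``/t0``."""
        with h5py.File(path, "w") as fh:
            fh.create_dataset("data", data=self.data)
            fh.create_dataset("fs", data=float(self.fs))
            fh.create_dataset("t0", data=float(self.t0))
            fh.create_dataset("channels", data=np.array(self.channel_names, dtype="S"))

    @classmethod
    def from_hdf5(cls, path) -> "Recording":
        with h5py.File(path, "r") as fh:
            names = [c.decode() for c in fh["channels"][()]]
            return cls(fh["data"][()], float(fh["fs"][()]), names, float(fh["t0"][()]))
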