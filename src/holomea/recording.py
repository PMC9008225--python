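"""Raw multichannel recording container with HDF5 persistence."""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .layout import MEALayout

__all__ = ["RawRecording"]


@dataclass
class RawRecording:
    """Sampled extracellular voltage on every recording electrode.

    ``signals`` is a (n_channels, n_samples) array in signal units (uV for
    the simulator); channels align with ``electrode_ids`` and with the
    layout's electrode order. Default sampling rate is 25 kHz.
    """

    signals: np.ndarray
    fs: float
    electrode_ids: list[str]
    layout: MEALayout | None = None
    session_id: str = "session0"

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.electrode_ids) != self.signals.shape[0]:
            raise ValueError("one electrode id per channel required")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel(self, electrode_id: str) -> np.ndarray:
        return self.signals[self.electrode_ids.index(electrode_id)]

    # -- persistence -----------------------------------------------------

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("signals", data=self.signals, compression="gzip")
            fh.attrs["fs"] = self.fs
            fh.attrs["session_id"] = self.session_id
            fh.create_dataset(
                "electrode_ids",
                data=np.array(self.electrode_ids, dtype=h5py.string_dtype()),
            )
            if self.layout is not None:
                grp = fh.create_group("layout")
                grp.attrs["n_rows"] = self.layout.n_rows
                grp.attrs["n_cols"] = self.layout.n_cols
                grp.attrs["pitch_um"] = self.layout.pitch
                grp.attrs["electrode_diameter_um"] = self.layout.electrode_diameter
                grp.create_dataset(
                    "excluded_positions",
                    data=np.asarray(self.layout.excluded_positions, int).reshape(-1, 2),
                )

    @classmethod
    def from_hdf5(cls, path) -> "RawRecording":
        with h5py.File(path, "r") as fh:
            signals = fh["signals"][...]
            fs = float(fh.attrs["fs"])
            session_id = str(fh.attrs["session_id"])
            electrode_ids = [s.decode() for s in fh["electrode_ids"][...]]
            layout = None
            if "layout" in fh:
                grp = fh["layout"]
                layout = MEALayout(
                    n_rows=int(grp.attrs["n_rows"]),
                    n_cols=int(grp.attrs["n_cols"]),
                    pitch=float(grp.attrs["pitch_um"]),
                    electrode_diameter=float(grp.attrs["electrode_diameter_um"]),
                    excluded_positions=tuple(
                        tuple(int(v) for v in row)
                        for row in grp["excluded_positions"][...]
                    ),
                )
        return cls(signals, fs, electrode_ids, layout, session_id)
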