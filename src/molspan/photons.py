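"""Photon record streams.

The atom of all fluorescence analysis: a time-ordered table of detection
events with macrotime (ps ticks), detection channel, microtime (ps since
the excitation pulse) and excitation source.

Channel encoding (uint8):
    0 = donor  parallel, 1 = donor  perpendicular,
    2 = acceptor parallel, 3 = acceptor perpendicular.
Source encoding: 0 = donor (green) excitation, 1 = acceptor (red).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CH_DONOR_PAR", "CH_DONOR_PERP", "CH_ACCEPTOR_PAR", "CH_ACCEPTOR_PERP",
    "SRC_GREEN", "SRC_RED",
    "PhotonStream",
]

CH_DONOR_PAR = 0
CH_DONOR_PERP = 1
CH_ACCEPTOR_PAR = 2
CH_ACCEPTOR_PERP = 3
SRC_GREEN = 0
SRC_RED = 1

PS_PER_S = 1_000_000_000_000


@dataclass
class PhotonStream:
    """Sorted photon arrival records.

    macrotime is in integer picosecond ticks, microtime in picoseconds
    relative to the excitation pulse (0 for continuous-wave streams where
    no sync exists, but the simulator stores the emission delay anyway).
    """

    macrotime: np.ndarray            # int64, ps
    channel: np.ndarray              # uint8
    microtime: np.ndarray            # uint16, ps
    source: np.ndarray               # uint8
    duration: float                  # s

    def __post_init__(self) -> None:
        self.macrotime = np.asarray(self.macrotime, dtype=np.int64)
        self.channel = np.asarray(self.channel, dtype=np.uint8)
        self.microtime = np.asarray(self.microtime, dtype=np.uint16)
        self.source = np.asarray(self.source, dtype=np.uint8)
        n = self.macrotime.size
        if not (self.channel.size == self.microtime.size == self.source.size == n):
            raise ValueError("all record columns must have equal length")
        if n > 1 and np.any(np.diff(self.macrotime) < 0):
            raise ValueError("macrotimes must be nondecreasing")
        if n and self.channel.max() > 3:
            raise ValueError("channel labels must be in {0, 1, 2, 3}")

    def __len__(self) -> int:
        return self.macrotime.size

    # -- masks ------------------------------------------------------------
    @property
    def is_donor(self) -> np.ndarray:
        return self.channel < 2

    @property
    def is_acceptor(self) -> np.ndarray:
        return self.channel >= 2

    @property
    def is_parallel(self) -> np.ndarray:
        return (self.channel % 2) == 0

    @property
    def times_s(self) -> np.ndarray:
        return self.macrotime / PS_PER_S

    def subset(self, mask: np.ndarray) -> "PhotonStream":
        return PhotonStream(self.macrotime[mask], self.channel[mask],
                            self.microtime[mask], self.source[mask], self.duration)

    # -- I/O ---------------------------------------------------------------
    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["duration_s"] = self.duration
            f.create_dataset("macrotime", data=self.macrotime)
            f.create_dataset("channel", data=self.channel)
            f.create_dataset("microtime", data=self.microtime)
            f.create_dataset("source", data=self.source)

    @classmethod
    def from_hdf5(cls, path) -> "PhotonStream":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(f["macrotime"][:], f["channel"][:], f["microtime"][:],
                       f["source"][:], float(f.attrs["duration_s"]))

    def to_tsv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame({
            "macrotime_ps": self.macrotime,
            "channel": self.channel,
            "microtime_ps": self.microtime,
            "source": self.source,
        })
        with open(path, "w") as fh:
            fh.write(f"# duration_s\t{self.duration}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PhotonStream":
        import pandas as pd

        with open(path) as fh:
            header = fh.readline()
            duration = float(header.strip().split("\t")[1])
            df = pd.read_csv(fh, sep="\t")
        return cls(df["macrotime_ps"].to_numpy(), df["channel"].to_numpy(),
                   df["microtime_ps"].to_numpy(), df["source"].to_numpy(), duration)

    @classmethod
    def merge(cls, streams: list["PhotonStream"]) -> "PhotonStream":
        """Merge-sort several streams covering the same observation window."""
        mt = np.concatenate([s.macrotime for s in streams])
        order = np.argsort(mt, kind="stable")
        return cls(
            mt[order],
            np.concatenate([s.channel for s in streams])[order],
            np.concatenate([s.microtime for s in streams])[order],
            np.concatenate([s.source for s in streams])[order],
            max(s.duration for s in streams),
        )
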