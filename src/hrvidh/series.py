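"""Tachogram container and plain-text I/O.

A tachogram is the sequence of R-R intervals (RRIs, in ms) as a function of
beat time (in seconds from the start of the recording).  The convention used
throughout the package is that ``rr[k]`` is the interval *ending* at
``time[k]``, so the cumulative sum of ``rr / 1000`` reproduces the beat
times of a recording that starts at t = 0.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd


@dataclasses.dataclass(frozen=True)
class BeatSeries:
    """One session's tachogram: beat times (s) and RR intervals (ms)."""

    time: np.ndarray
    rr: np.ndarray

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        rr = np.asarray(self.rr, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "rr", rr)
        if time.ndim != 1 or rr.ndim != 1 or time.shape != rr.shape:
            raise ValueError("time and rr must be 1-D arrays of equal length")
        if time.size and np.any(np.diff(time) <= 0):
            raise ValueError("beat times must be strictly increasing")
        if np.any(rr <= 0):
            raise ValueError("all RR intervals must be positive")

    def __len__(self) -> int:
        return int(self.time.size)

    @property
    def duration(self) -> float:
        """Time of the last beat (s); 0 for an empty series."""
        return float(self.time[-1]) if len(self) else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time, "rr_ms": self.rr})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BeatSeries":
        df = pd.read_csv(path)
        missing = {"time_s", "rr_ms"} - set(df.columns)
        if missing:
            raise ValueError(f"tachogram CSV {path} lacks columns {sorted(missing)}")
        return cls(df["time_s"].to_numpy(), df["rr_ms"].to_numpy())

    @classmethod
    def from_beat_times(cls, times) -> "BeatSeries":
        """Build a series from beat timestamps only; RRIs are first differences.

        The first timestamp anchors t = 0 of the interval sequence and is
        dropped (it has no preceding interval).
        """
        times = np.asarray(times, dtype=float)
        if times.size < 2:
            raise ValueError("need at least two beat times to form intervals")
        rr = np.diff(times) * 1000.0
        return cls(times[1:], rr)
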