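"""Time series and trajectory containers shared across modules."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TimeSeries", "Trajectory"]


@dataclass
class TimeSeries:
    """A labelled scalar time series (times in minutes)."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""
    unit: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    @property
    def sampling_interval(self) -> float:
        if self.times.size < 2:
            raise ValueError("need at least two samples")
        return float(np.median(np.diff(self.times)))


@dataclass
class Trajectory:
    """Timestamped 2-D positions (times in minutes, positions in μm)."""

    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must have shape (n, 2)")
        if self.times.shape != (self.positions.shape[0],):
            raise ValueError("times and positions must have matching lengths")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    @property
    def displacements(self) -> np.ndarray:
        """Per-step displacement vectors, shape (n-1, 2)."""
        return np.diff(self.positions, axis=0)

    @property
    def path_length(self) -> float:
        """Total path length in μm."""
        return float(np.sum(np.linalg.norm(self.displacements, axis=1)))

    @property
    def net_displacement(self) -> float:
        """Straight-line start-to-end distance in μm."""
        return float(np.linalg.norm(self.positions[-1] - self.positions[0]))
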