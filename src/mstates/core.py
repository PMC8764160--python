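"""Core containers shared across the pipeline.

The central object is :class:`Recording`: a channels-by-samples potential
matrix in microvolts with sampling-rate and montage metadata.  Everything
downstream (epoching, global field power, clustering, backfitting) consumes
and produces this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = ["Recording", "scalp_positions", "default_channel_names"]


def default_channel_names(n_channels: int) -> list[str]:
    """Generic electrode labels E001..E0NN (dense-array net convention)."""
    width = max(3, len(str(n_channels)))
    return [f"E{i + 1:0{width}d}" for i in range(n_channels)]


def scalp_positions(n_channels: int) -> np.ndarray:
    """Quasi-uniform electrode positions on the upper unit hemisphere.

    Uses a Fibonacci lattice restricted to z >= 0.  Coordinate convention:
    +x right, +y anterior, +z vertex.  Returns an (n_channels, 3) array of
    unit vectors, ordered front-to-back within the lattice ordering.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    golden = np.pi * (3.0 - np.sqrt(5.0))
    i = np.arange(n_channels)
    # z from just below vertex down to just above the equator
    z = 1.0 - (i + 0.5) / n_channels
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    theta = golden * i
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return pos


@dataclass
class Recording:
    """Multichannel EEG excerpt.

    Parameters
    ----------
    data : ndarray, shape (C, T)
        Scalp potentials in microvolts, one row per channel.
    sampling_rate_hz : float
        Sampling rate in Hz.
    channel_names : list of str
        Unique channel identifiers, length C.
    channel_positions : ndarray, shape (C, 3), optional
        3D electrode coordinates (unit sphere).  Required only for
        distance-based channel interpolation.
    reference : {"original", "average"}
        Whether the data have been re-referenced to the common average.
    """

    data: np.ndarray
    sampling_rate_hz: float
    channel_names: list[str] = field(default_factory=list)
    channel_positions: Optional[np.ndarray] = None
    reference: str = "original"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2D channels x samples array")
        c, t = self.data.shape
        if c < 2:
            raise ValueError("a Recording needs at least 2 channels")
        if t < 1:
            raise ValueError("a Recording needs at least 1 sample")
        if not self.channel_names:
            self.channel_names = default_channel_names(c)
        if len(self.channel_names) != c:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {c} channels"
            )
        if len(set(self.channel_names)) != c:
            raise ValueError("channel names must be unique")
        if self.channel_positions is not None:
            self.channel_positions = np.asarray(self.channel_positions, dtype=float)
            if self.channel_positions.shape != (c, 3):
                raise ValueError("channel_positions must have shape (C, 3)")
        if self.reference not in ("original", "average"):
            raise ValueError("reference must be 'original' or 'average'")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def copy_with(self, **changes) -> "Recording":
        return replace(self, **changes)
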