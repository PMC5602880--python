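"""Core raster types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TwoChannelImage:
    """Paired green (lamina) and red (chromatin) rasters.

    ``P`` is the global intensity ceiling of the whole data set; when a
    single image is processed in isolation it defaults to the maximum over
    both channels.
    """

    green: np.ndarray
    red: np.ndarray
    P: float = 0.0
    pixel_size: float = 1.0  # micrometres per pixel, metadata only

    def __post_init__(self) -> None:
        self.green = np.asarray(self.green, dtype=float)
        self.red = np.asarray(self.red, dtype=float)
        if self.green.shape != self.red.shape:
            raise ValueError(
                f"channel shape mismatch: {self.green.shape} vs {self.red.shape}"
            )
        if self.P <= 0:
            self.P = float(max(self.green.max(initial=0.0), self.red.max(initial=0.0)))
        if self.P <= 0:
            raise ValueError("intensity ceiling P must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.green.shape


@dataclass
class SeedSet:
    """Seed locations (row, col) with their smoothed distance-map values."""

    locations: list[tuple[int, int]] = field(default_factory=list)
    values: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.locations) != len(self.values):
            raise ValueError("locations and values length mismatch")
        if len(set(self.locations)) != len(self.locations):
            raise ValueError("seed locations must be pairwise distinct")

    def __len__(self) -> int:
        return len(self.locations)

    def __iter__(self):
        return iter(zip(self.locations, self.values))


def as_binary(mask: np.ndarray) -> np.ndarray:
    """Coerce a raster to a {0,1} uint8 mask."""
    return (np.asarray(mask) > 0).astype(np.uint8)


def relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    """Renumber nonzero labels to 1..K preserving first-appearance order."""
    labels = np.asarray(labels)
    out = np.zeros_like(labels, dtype=np.int32)
    ids = [int(v) for v in np.unique(labels) if v != 0]
    for new, old in enumerate(sorted(ids), start=1):
        out[labels == old] = new
    return out
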