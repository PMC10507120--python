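"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ImageStack", "SyntheticGroundTruth", "PlacementError"]


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed without overlap in a frame."""


@dataclass
class ImageStack:
    """A named multi-channel pixel grid (channels, height, width).

    Pixel grids are 0-based; coordinates are (y, x) with the origin at the
    top-left, x increasing rightwards and y downwards. Boxes elsewhere in the
    package are half-open ``[x0, x1) x [y0, y1)`` in this frame.
    """

    data: np.ndarray
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("ImageStack data must be 3-D (channels, H, W)")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel names for {self.data.shape[0]} planes"
            )
        self.channels = tuple(self.channels)

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial shape (H, W)."""
        return self.data.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        """The 2-D plane for channel *name*."""
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in stack") from None
        return self.data[idx]

    def copy(self) -> "ImageStack":
        return ImageStack(self.data.copy(), self.channels)


@dataclass
class SyntheticGroundTruth:
    """Generator ground truth for one synthetic frame or ROI.

    ``cells`` has one row per placed cell with at least ``cell_id`` (dense
    1..N), centroid ``y``/``x`` (px), ``cell_type``, nuclear geometry, and —
    for ion-count ROIs — the true per-marker mean counts in ``mean_<marker>``
    columns. ``hot_pixels`` lists injected detector artifacts as
    (channel, y, x, value).
    """

    cells: pd.DataFrame
    hot_pixels: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["channel", "y", "x", "value"])
    )
    background: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    shape: tuple[int, int] = (0, 0)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def validate(self) -> None:
        if self.n_cells:
            ids = np.sort(self.cells["cell_id"].to_numpy())
            if not np.array_equal(ids, np.arange(1, self.n_cells + 1)):
                raise ValueError("cell ids must be dense 1..N")
        if len(self.hot_pixels):
            h, w = self.shape
            y = self.hot_pixels["y"].to_numpy()
            x = self.hot_pixels["x"].to_numpy()
            if (y < 0).any() or (y >= h).any() or (x < 0).any() or (x >= w).any():
                raise ValueError("hot pixel outside image bounds")
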