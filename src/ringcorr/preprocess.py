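"""Masking and grid partitioning of super-resolution images.

An image is reduced to a region of interest by thresholding (optionally after
mean-filter smoothing) and/or manual mask edits, then tiled into rectangular
grids.  Grids whose mask region is entirely background are discarded; all
later stages operate on the surviving grids independently.

Conventions used throughout the package: arrays are indexed ``[row, col]``,
0-based, with half-open pixel intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np
from scipy import ndimage


class EmptyMaskError(ValueError):
    """Raised when a mask operation would produce a mask with no foreground."""


@dataclass
class MaskedImage:
    """One- or two-channel image plus binary mask and physical pixel pitch.

    Parameters
    ----------
    channels
        List of 2-D intensity arrays, all of identical shape.
    mask
        2-D boolean array of the same shape; ``True`` marks foreground.
    pixels_per_um
        Physical sampling density in pixels per micrometre (> 0).
    """

    channels: list
    mask: np.ndarray
    pixels_per_um: float

    def __post_init__(self) -> None:
        self.channels = [np.asarray(c) for c in self.channels]
        self.mask = np.asarray(self.mask, dtype=bool)
        if not 1 <= len(self.channels) <= 2:
            raise ValueError("MaskedImage supports 1 or 2 channels")
        shape = self.channels[0].shape
        if any(c.shape != shape for c in self.channels) or self.mask.shape != shape:
            raise ValueError("channel and mask shapes must all match")
        if len(shape) != 2:
            raise ValueError("channels must be 2-D")
        if not self.pixels_per_um > 0:
            raise ValueError("pixels_per_um must be positive")

    @property
    def shape(self) -> tuple:
        return self.channels[0].shape

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def step_um(self) -> float:
        """Physical size of one pixel in micrometres."""
        return 1.0 / self.pixels_per_um


@dataclass
class Grid:
    """A rectangular tile of a :class:`MaskedImage` containing mask pixels.

    ``rows`` and ``cols`` are half-open ``(start, stop)`` pixel intervals in
    the parent image.
    """

    rows: tuple
    cols: tuple
    parent: MaskedImage = field(repr=False)
    index: int

    @property
    def shape(self) -> tuple:
        return (self.rows[1] - self.rows[0], self.cols[1] - self.cols[0])

    def channel(self, i: int) -> np.ndarray:
        return self.parent.channels[i][
            self.rows[0] : self.rows[1], self.cols[0] : self.cols[1]
        ]

    @property
    def mask(self) -> np.ndarray:
        return self.parent.mask[
            self.rows[0] : self.rows[1], self.cols[0] : self.cols[1]
        ]


def make_mask(
    image: np.ndarray, threshold: float, smooth_radius: int = 0
) -> np.ndarray:
    """Threshold an intensity image into a binary mask.

    A mean filter of the given radius (window ``2r + 1``; radius 0 disables
    smoothing) is applied before comparison; pixels whose smoothed value is
    ``>= threshold`` become foreground.

    Raises
    ------
    EmptyMaskError
        If no pixel survives the threshold.
    """
    image = np.asarray(image, dtype=float)
    if smooth_radius < 0:
        raise ValueError("smooth_radius must be >= 0")
    radius = int(round(smooth_radius))
    if radius > 0:
        image = ndimage.uniform_filter(image, size=2 * radius + 1)
    mask = image >= threshold
    if not mask.any():
        raise EmptyMaskError("threshold leaves no foreground pixel")
    return mask


def edit_mask(
    mask: np.ndarray,
    add: Iterable[tuple] = (),
    erase: Iterable[tuple] = (),
) -> np.ndarray:
    """Apply manual add/erase edits to a binary mask.

    ``erase`` wins over ``add`` when a coordinate appears in both sets.
    Coordinates are ``(row, col)`` pairs and must be in bounds.
    """
    out = np.asarray(mask, dtype=bool).copy()
    for name, coords, value in (("add", add, True), ("erase", erase, False)):
        for r, c in coords:
            if not (0 <= r < out.shape[0] and 0 <= c < out.shape[1]):
                raise IndexError(f"{name} coordinate {(r, c)} out of bounds")
            out[r, c] = value
    return out


def partition_grids(
    img: MaskedImage,
    grid_height_px: int,
    grid_width_px: Union[int, str] = "image-width",
) -> list:
    """Tile the image into grids and drop background-only tiles.

    Tiles are laid out from the top-left in row-major order.  A trailing
    partial tile at the bottom/right edge is kept if it contains mask
    pixels, so no foreground is silently discarded.  Returned grids carry
    sequential indices in row-major order.
    """
    nrows, ncols = img.shape
    if grid_width_px == "image-width":
        grid_width_px = ncols
    grid_height_px = int(grid_height_px)
    grid_width_px = int(grid_width_px)
    if grid_height_px < 2 or grid_width_px < 2:
        raise ValueError("grid dimensions must be >= 2 px")

    grids = []
    index = 0
    for r0 in range(0, nrows, grid_height_px):
        r1 = min(r0 + grid_height_px, nrows)
        for c0 in range(0, ncols, grid_width_px):
            c1 = min(c0 + grid_width_px, ncols)
            if img.mask[r0:r1, c0:c1].any():
                grids.append(Grid(rows=(r0, r1), cols=(c0, c1), parent=img, index=index))
                index += 1
    return grids
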