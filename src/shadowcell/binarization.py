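"""Adaptive 16-region binarization of a shadow image.

The raster is divided into a 4×4 grid of tiles.  Each tile contributes its
mean intensity, and the per-tile *determination value* is that mean minus an
empirically chosen, cell-line-specific gray offset.  A pixel strictly below
its tile's determination value becomes a cell-candidate; everything else is
background.  Local (per-tile) thresholds compensate the slowly varying
illumination of an LED/pinhole source across the sensor.

Cells cast darker-than-background shadows, so candidates are low-intensity
pixels.  The classification is recorded in a separate :class:`LabelPlane`
using the sentinel intensities 96 (candidate), 175 (cluster member),
60 (cell center) and 255 (background), leaving the raw image untouched —
a raw pixel may legitimately equal a sentinel value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .image_io import GrayImage

__all__ = [
    "CANDIDATE",
    "CLUSTER",
    "CENTER",
    "BACKGROUND",
    "BinarizationConfig",
    "LabelPlane",
    "compute_region_means",
    "compute_determination_values",
    "binarize",
]

CANDIDATE = 96
CLUSTER = 175
CENTER = 60
BACKGROUND = 255


@dataclass(frozen=True)
class BinarizationConfig:
    """Tiling and offset for adaptive thresholding.

    ``gray_offset`` has no universal default: it is an empirical constant per
    cell line (intensity units on the 8-bit scale).  The 4×4 grid yields the
    canonical 16 regions.
    """

    gray_offset: float
    grid_rows: int = 4
    grid_cols: int = 4

    def __post_init__(self) -> None:
        if self.gray_offset < 0:
            raise ConfigurationError("gray_offset must be >= 0")
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ConfigurationError("grid dimensions must be >= 1")


@dataclass
class LabelPlane:
    """Per-pixel state plane, same shape as the source image.

    After binarization states are a subset of {96, 255}; after clustering and
    center marking, {60, 255}.
    """

    states: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.uint8)
        if self.states.ndim != 2:
            raise ConfigurationError("label plane must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self.states.shape)  # type: ignore[return-value]

    def to_image(self) -> GrayImage:
        """Render the sentinel values as an 8-bit debug image."""
        return GrayImage(self.states.copy())


def tile_bounds(length: int, n_tiles: int) -> list[tuple[int, int]]:
    """Half-open [start, stop) extents of ``n_tiles`` tiles along one axis.

    Remainder pixels are absorbed by the last tile so exactly ``n_tiles``
    tiles always partition the axis.
    """
    base = length // n_tiles
    if base < 1:
        raise ConfigurationError(
            f"axis of length {length} cannot be split into {n_tiles} tiles"
        )
    edges = [i * base for i in range(n_tiles)] + [length]
    return [(edges[i], edges[i + 1]) for i in range(n_tiles)]


def compute_region_means(image: GrayImage, config: BinarizationConfig) -> np.ndarray:
    """Mean intensity of each tile, as a (grid_rows, grid_cols) float array."""
    rows = tile_bounds(image.height, config.grid_rows)
    cols = tile_bounds(image.width, config.grid_cols)
    means = np.empty((config.grid_rows, config.grid_cols), dtype=np.float64)
    px = image.pixels
    for i, (r0, r1) in enumerate(rows):
        for j, (c0, c1) in enumerate(cols):
            means[i, j] = px[r0:r1, c0:c1].mean()
    return means


def compute_determination_values(
    means: np.ndarray, config: BinarizationConfig
) -> np.ndarray:
    """Per-tile threshold: tile mean minus the gray offset, clamped to [0, 255]."""
    means = np.asarray(means, dtype=np.float64)
    if means.shape != (config.grid_rows, config.grid_cols):
        raise ConfigurationError(
            f"means shape {means.shape} does not match grid "
            f"({config.grid_rows}, {config.grid_cols})"
        )
    return np.clip(means - config.gray_offset, 0.0, 255.0)


def binarize(
    image: GrayImage, thresholds: np.ndarray, config: BinarizationConfig
) -> LabelPlane:
    """Classify every pixel against its tile's determination value.

    Strictly below the threshold → CANDIDATE (96); at or above → BACKGROUND
    (255).  Equality goes to background: the conservative reading that admits
    fewer false candidates.  The source image is never modified.
    """
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if thresholds.shape != (config.grid_rows, config.grid_cols):
        raise ConfigurationError(
            f"thresholds shape {thresholds.shape} does not match grid "
            f"({config.grid_rows}, {config.grid_cols})"
        )
    rows = tile_bounds(image.height, config.grid_rows)
    cols = tile_bounds(image.width, config.grid_cols)
    # Per-pixel threshold map assembled tile by tile (16 slices).
    thresh_map = np.empty(image.shape, dtype=np.float64)
    for i, (r0, r1) in enumerate(rows):
        for j, (c0, c1) in enumerate(cols):
            thresh_map[r0:r1, c0:c1] = thresholds[i, j]
    states = np.where(image.pixels < thresh_map, CANDIDATE, BACKGROUND)
    return LabelPlane(states.astype(np.uint8))


def binarize_image(image: GrayImage, config: BinarizationConfig) -> LabelPlane:
    """Convenience: region means → determination values → binarize."""
    means = compute_region_means(image, config)
    thresholds = compute_determination_values(means, config)
    return binarize(image, thresholds, config)
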