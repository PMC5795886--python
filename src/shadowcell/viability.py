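"""Peak-to-peak-distance (PPD) viability classification.

The shadow of a cell is a radial diffraction pattern with a zero-order peak
and first-order valley; its contrast is summarized by the PPD — the
difference between the highest and lowest pixel intensity in an 11×11 window
centered on the detected cell, measured on the *unmodified* image (the label
plane is computed on a duplicate).  Dead cells flatten as their membrane
ruptures, attenuate the light less, and cast patterns with contrast up to
3.54× that of live cells, so a cell is called DEAD when its PPD reaches a
per-cell-line viability constant, LIVE below it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .clustering import CellDetection, CellState
from .errors import BoundsError, ConfigurationError
from .image_io import GrayImage

__all__ = [
    "ViabilityConfig",
    "compute_ppd",
    "classify_viability",
    "classify_detections",
    "calibrate_ppd_threshold",
]


@dataclass(frozen=True)
class ViabilityConfig:
    """Window size and per-cell-line PPD threshold.

    ``ppd_threshold`` is the empirical cell-viability constant (intensity
    units); no canonical per-line values exist, see
    :func:`calibrate_ppd_threshold` for a labeled-sample helper.
    """

    ppd_threshold: float
    window_side: int = 11

    def __post_init__(self) -> None:
        if self.window_side < 3 or self.window_side % 2 == 0:
            raise ConfigurationError("window_side must be odd and >= 3")
        if not (0.0 < self.ppd_threshold <= 255.0):
            raise ConfigurationError("ppd_threshold must lie in (0, 255]")


def compute_ppd(
    image: GrayImage, center: tuple[int, int], config: ViabilityConfig
) -> int:
    """Max minus min intensity in the window centered on ``center``.

    Windows that extend past the image border are clipped rather than padded
    (padding would fabricate intensities into the extrema).
    """
    r, c = center
    if not (0 <= r < image.height and 0 <= c < image.width):
        raise BoundsError(f"center {center} outside image {image.shape}")
    half = config.window_side // 2
    window = image.pixels[
        max(0, r - half) : min(image.height, r + half + 1),
        max(0, c - half) : min(image.width, c + half + 1),
    ]
    return int(window.max()) - int(window.min())


def classify_viability(ppd: float, config: ViabilityConfig) -> CellState:
    """DEAD iff ppd >= threshold (dead cells have the higher contrast)."""
    if ppd < 0:
        raise ValueError("ppd must be >= 0")
    return CellState.DEAD if ppd >= config.ppd_threshold else CellState.LIVE


def classify_detections(
    image: GrayImage, detections: Iterable[CellDetection], config: ViabilityConfig
) -> tuple[int, int]:
    """Fill ppd/state of every detection in place; return (n_live, n_dead)."""
    n_live = n_dead = 0
    for det in detections:
        det.ppd = compute_ppd(image, (det.center_row, det.center_col), config)
        det.state = classify_viability(det.ppd, config)
        if det.state is CellState.LIVE:
            n_live += 1
        else:
            n_dead += 1
    return n_live, n_dead


def calibrate_ppd_threshold(
    live_ppds: Sequence[float], dead_ppds: Sequence[float]
) -> float:
    """Midpoint between the mean live and mean dead PPD of a labeled sample.

    Convenience only — in practice the viability constant is established per
    cell line from reference measurements.
    """
    if len(live_ppds) == 0 or len(dead_ppds) == 0:
        raise ConfigurationError("both classes must be represented")
    lo = float(np.mean(live_ppds))
    hi = float(np.mean(dead_ppds))
    if hi <= lo:
        raise ConfigurationError(
            "dead PPDs must exceed live PPDs for a meaningful threshold"
        )
    return (lo + hi) / 2.0
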