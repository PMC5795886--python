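"""Reading and writing 8-bit grayscale shadow images and analysis reports.

Shadow images from a lens-free imager are intrinsically monochrome (a single
blue LED illuminates the sensor), so everything downstream works on a 2-D
8-bit intensity raster.  Coordinates are row-major, 0-based ``(row, col)``
with the origin at the top-left pixel.

Supported image formats: PNG, TIFF and binary PGM (P5) at 8 bits per pixel.
Multi-channel inputs are reduced to one channel by the arithmetic mean of the
channels, rounded half up; 16-bit inputs are rejected unless an explicit
downscale flag is given (the sentinel thresholds used by the analysis are
defined on the 8-bit scale).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import imageio.v3 as iio
import numpy as np

from .errors import FormatError

__all__ = [
    "GrayImage",
    "AnalysisResult",
    "read_gray_image",
    "write_gray_image",
    "write_result",
    "read_result",
    "write_detections_csv",
]

RESULT_SCHEMA = "shadowcell-result/1"

_SUPPORTED_SUFFIXES = {".png", ".tif", ".tiff", ".pgm"}


@dataclass(frozen=True)
class GrayImage:
    """A 2-D 8-bit grayscale raster.

    ``pixels`` is always a C-contiguous ``uint8`` array; construction
    validates shape and value range.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise FormatError(f"expected a non-empty 2-D raster, got shape {arr.shape}")
        if arr.dtype != np.uint8:
            if not np.issubdtype(arr.dtype, np.integer):
                raise FormatError(f"pixel dtype must be integral, got {arr.dtype}")
            if arr.min() < 0 or arr.max() > 255:
                raise FormatError("pixel intensities must lie in [0, 255]")
            arr = arr.astype(np.uint8)
        object.__setattr__(self, "pixels", np.ascontiguousarray(arr))

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def copy(self) -> "GrayImage":
        return GrayImage(self.pixels.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GrayImage):
            return NotImplemented
        return self.pixels.shape == other.pixels.shape and bool(
            np.array_equal(self.pixels, other.pixels)
        )


def _reduce_channels(arr: np.ndarray) -> np.ndarray:
    """Mean over channels, rounded half up. Alpha (4th channel) is dropped."""
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        arr = np.floor(arr.astype(np.float64).mean(axis=2) + 0.5)
    return arr


def read_gray_image(path: str | Path, *, allow_16bit: bool = False) -> GrayImage:
    """Read an 8-bit grayscale image from PNG/TIFF/PGM.

    Parameters
    ----------
    path:
        File to read.  Must exist and carry one of the supported suffixes.
    allow_16bit:
        When True, 16-bit inputs are downscaled by 257 with round-half-up
        (so 65535 maps to 255).  Without the flag, 16-bit input is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise FormatError(f"unsupported image format: {path.suffix!r}")
    arr = np.asarray(iio.imread(path))
    if arr.dtype == np.uint16:
        if not allow_16bit:
            raise FormatError(
                "16-bit input rejected: pass allow_16bit=True to downscale to 8-bit"
            )
        arr = np.floor(arr.astype(np.float64) / 257.0 + 0.5)
    elif arr.dtype != np.uint8 and not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"unsupported pixel dtype: {arr.dtype}")
    arr = _reduce_channels(arr)
    return GrayImage(np.asarray(arr, dtype=np.float64).round().astype(np.uint8))


def write_gray_image(image: GrayImage, path: str | Path) -> None:
    """Write an 8-bit grayscale image; format chosen from the suffix."""
    path = Path(path)
    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise FormatError(f"unsupported image format: {path.suffix!r}")
    iio.imwrite(path, image.pixels)


@dataclass
class AnalysisResult:
    """Complete report for one analyzed image.

    Invariants: ``n_live + n_dead == n_total``; ``0 <= viability <= 100``
    when defined (``None`` flags an undefined viability, e.g. zero cells).
    ``size_distribution`` is a histogram of the bounding-box diagonal of each
    detection, in pixels, as ``{"bin_edges": [...], "counts": [...]}``.
    """

    n_total: int
    n_live: int
    n_dead: int
    concentration: float | None = None
    viability: float | None = None
    size_distribution: dict[str, list[float]] = field(default_factory=dict)
    detections: list[Any] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_live + self.n_dead != self.n_total:
            raise ValueError("n_live + n_dead must equal n_total")
        if self.viability is not None and not (0.0 <= self.viability <= 100.0):
            raise ValueError("viability must lie in [0, 100] when defined")

    def to_dict(self) -> dict[str, Any]:
        return {
            "schema": RESULT_SCHEMA,
            "n_total": self.n_total,
            "n_live": self.n_live,
            "n_dead": self.n_dead,
            "concentration": self.concentration,
            "viability": self.viability,
            "size_distribution": self.size_distribution,
            "detections": [
                {
                    "id": i,
                    "row": d.center_row,
                    "col": d.center_col,
                    "bbox_top": d.bbox_top,
                    "bbox_left": d.bbox_left,
                    "bbox_h": d.bbox_height,
                    "bbox_w": d.bbox_width,
                    "ppd": d.ppd,
                    "state": d.state.name,
                }
                for i, d in enumerate(self.detections)
            ],
        }


def write_result(result: AnalysisResult, path: str | Path) -> None:
    """Serialize an :class:`AnalysisResult` to a versioned JSON document."""
    Path(path).write_text(json.dumps(result.to_dict(), indent=2) + "\n")


def read_result(path: str | Path) -> AnalysisResult:
    """Read back a JSON report written by :func:`write_result`."""
    from .clustering import CellDetection, CellState  # deferred: avoids import cycle

    doc = json.loads(Path(path).read_text())
    if doc.get("schema") != RESULT_SCHEMA:
        raise FormatError(f"unknown result schema: {doc.get('schema')!r}")
    detections = [
        CellDetection(
            center_row=d["row"],
            center_col=d["col"],
            bbox_top=d["bbox_top"],
            bbox_left=d["bbox_left"],
            bbox_height=d["bbox_h"],
            bbox_width=d["bbox_w"],
            ppd=d["ppd"],
            state=CellState[d["state"]],
        )
        for d in doc["detections"]
    ]
    return AnalysisResult(
        n_total=doc["n_total"],
        n_live=doc["n_live"],
        n_dead=doc["n_dead"],
        concentration=doc["concentration"],
        viability=doc["viability"],
        size_distribution=doc["size_distribution"],
        detections=detections,
    )


def write_detections_csv(detections: Sequence[Any], path: str | Path) -> None:
    """Write a per-detection table: id,row,col,bbox_h,bbox_w,ppd,state."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "row", "col", "bbox_h", "bbox_w", "ppd", "state"])
        for i, d in enumerate(detections):
            writer.writerow(
                [i, d.center_row, d.center_col, d.bbox_height, d.bbox_width,
                 d.ppd if d.ppd is not None else "", d.state.name]
            )
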