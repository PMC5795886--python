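"""End-to-end analysis: binarize → cluster → count → PPD → viability → report.

The photographed image is conceptually duplicated: the label plane (and
everything derived from it) is computed from one copy, while the PPD is read
from the untouched second copy.  Here that contract is honored by keeping
all pixel state in a separate :class:`~shadowcell.binarization.LabelPlane`
and never writing to the input raster.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml

from .binarization import BinarizationConfig, binarize_image
from .clustering import count_cells, grow_clusters, mark_centers
from .errors import ConfigurationError
from .image_io import AnalysisResult, GrayImage, write_gray_image
from .metrics import (
    ConcentrationMode,
    ConcentrationParams,
    ViabilityCounts,
    concentration,
    viability_percent,
)
from .viability import ViabilityConfig, classify_detections

__all__ = ["PipelineConfig", "analyze", "load_cell_line_config", "config_for_cell_line"]

SIZE_BIN_EDGES = list(np.arange(0.0, 65.0, 5.0))  # px, bbox-diagonal histogram


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one analysis run needs.

    ``concentration`` may be None (counts only).  In AREA_VOLUME mode with no
    explicit FOV area, the area is derived from the image dimensions and
    ``pixel_pitch_um``.
    """

    binarization: BinarizationConfig
    viability: ViabilityConfig
    concentration: ConcentrationParams | None = None
    pixel_pitch_um: float = 2.2
    cell_line: str | None = None
    debug_dir: str | Path | None = None


def _size_distribution(detections) -> dict[str, list[float]]:
    diagonals = [float(np.hypot(d.bbox_height, d.bbox_width)) for d in detections]
    counts, edges = np.histogram(diagonals, bins=SIZE_BIN_EDGES)
    return {"bin_edges": [float(e) for e in edges], "counts": [int(c) for c in counts]}


def analyze(image: GrayImage, config: PipelineConfig) -> AnalysisResult:
    """Run the full analysis on one image; deterministic for fixed inputs."""
    debug_dir = Path(config.debug_dir) if config.debug_dir else None
    if debug_dir:
        debug_dir.mkdir(parents=True, exist_ok=True)

    plane = binarize_image(image, config.binarization)
    if debug_dir:
        write_gray_image(plane.to_image(), debug_dir / "binarized.png")

    clusters = grow_clusters(plane)
    if debug_dir:
        write_gray_image(plane.to_image(), debug_dir / "clusters.png")

    final_plane, detections = mark_centers(plane, clusters)
    if debug_dir:
        write_gray_image(final_plane.to_image(), debug_dir / "centers.png")

    n_live, n_dead = classify_detections(image, detections, config.viability)
    n_total = count_cells(detections)

    conc = None
    if config.concentration is not None:
        params = config.concentration
        if params.mode is ConcentrationMode.AREA_VOLUME and params.fov_area_mm2 is None:
            area = image.height * image.width * config.pixel_pitch_um**2 * 1e-6
            params = replace(params, fov_area_mm2=area)
        conc = concentration(n_total, params)

    viability = None
    if n_total > 0:
        viability = viability_percent(
            ViabilityCounts(n_total=n_total, n_live=n_live, n_dead=n_dead),
            mode="standard",
        )

    return AnalysisResult(
        n_total=n_total,
        n_live=n_live,
        n_dead=n_dead,
        concentration=conc,
        viability=viability,
        size_distribution=_size_distribution(detections),
        detections=detections,
    )


def load_cell_line_config(path: str | Path) -> dict[str, dict[str, float]]:
    """Load a cell-line constants file (YAML or JSON).

    Layout: ``{cell_line_name: {gray_offset: <float>, ppd_threshold: <float>}}``.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"malformed cell-line config: {path}")
    return data


def config_for_cell_line(
    cell_lines: dict[str, dict[str, float]],
    name: str,
    concentration_params: ConcentrationParams | None = None,
    **overrides,
) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a cell-line constants table."""
    if name not in cell_lines:
        raise ConfigurationError(f"unknown cell line: {name!r}")
    entry = cell_lines[name]
    try:
        gray_offset = float(entry["gray_offset"])
        ppd_threshold = float(entry["ppd_threshold"])
    except KeyError as exc:
        raise ConfigurationError(f"cell line {name!r} missing constant: {exc}") from exc
    return PipelineConfig(
        binarization=BinarizationConfig(gray_offset=gray_offset),
        viability=ViabilityConfig(ppd_threshold=ppd_threshold),
        concentration=concentration_params,
        cell_line=name,
        **overrides,
    )
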