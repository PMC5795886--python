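"""Matrix-expansion clustering, size rules and cell-center marking.

Candidate pixels are grown into *cluster matrices* by repeatedly centering a
3×3 window on every newly absorbed candidate — which is exactly the closure
of 8-connectivity, so each cluster is one 8-connected component of the
candidate mask.  The scan starts at the top-left pixel and proceeds in
raster order, so clusters are reported in raster order of their seed pixel.

The bounding box of the grown matrix then drives the size rules:

* fits in 20×20 px            → one cell (SINGLET)
* else fits in 20×40 / 40×20  → two attached cells (DOUBLET); two overlapping
                                20-px boxes are tiled along the long axis
* anything larger             → noise (clumps, islands, contaminants)

Finally each accepted cell contributes one center pixel (sentinel 60) on an
otherwise background (255) plane; the number of center pixels is the cell
count.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .binarization import BACKGROUND, CANDIDATE, CENTER, CLUSTER, LabelPlane

__all__ = [
    "ClusterKind",
    "CellState",
    "ClusterMatrix",
    "CellDetection",
    "grow_clusters",
    "classify_cluster",
    "mark_centers",
    "count_cells",
    "SINGLET_MAX",
    "DOUBLET_MAX",
]

SINGLET_MAX = 20  # px: max bbox side for a single cell
DOUBLET_MAX = 40  # px: max long side for two attached cells


class ClusterKind(Enum):
    SINGLET = "singlet"
    DOUBLET = "doublet"
    NOISE = "noise"


class CellState(Enum):
    LIVE = "live"
    DEAD = "dead"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ClusterMatrix:
    """Bounding box and membership of one grown cluster."""

    bbox_top: int
    bbox_left: int
    bbox_height: int
    bbox_width: int
    member_count: int

    def __post_init__(self) -> None:
        if self.bbox_height < 1 or self.bbox_width < 1 or self.member_count < 1:
            raise ValueError("cluster must have positive extent and members")


@dataclass
class CellDetection:
    """One detected cell: its center, bounding box, PPD and live/dead call.

    For a doublet, the bbox is the cell's assigned 20-px half-box, not the
    full cluster box.  ``ppd`` is filled by the viability stage.
    """

    center_row: int
    center_col: int
    bbox_top: int
    bbox_left: int
    bbox_height: int
    bbox_width: int
    ppd: float | None = None
    state: CellState = CellState.UNCLASSIFIED


_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def grow_clusters(plane: LabelPlane) -> list[ClusterMatrix]:
    """Grow every candidate pixel into its cluster matrix.

    The plane is scanned in raster order; each unabsorbed candidate seeds a
    3×3 expansion that chains until no window contains a fresh candidate.
    Absorbed pixels are relabeled CLUSTER (175) in place.  Clusters are
    returned in raster order of their seed pixel.
    """
    states = plane.states
    coords = np.argwhere(states == CANDIDATE)  # row-major, i.e. raster order
    remaining = set(map(tuple, coords.tolist()))
    clusters: list[ClusterMatrix] = []
    for seed in map(tuple, coords.tolist()):
        if seed not in remaining:
            continue
        remaining.discard(seed)
        stack = [seed]
        top, left = seed
        bottom, right = seed
        count = 0
        while stack:
            r, c = stack.pop()
            count += 1
            top = min(top, r)
            bottom = max(bottom, r)
            left = min(left, c)
            right = max(right, c)
            for dr, dc in _NEIGHBORS:
                nb = (r + dr, c + dc)
                if nb in remaining:
                    remaining.discard(nb)
                    stack.append(nb)
        clusters.append(
            ClusterMatrix(
                bbox_top=top,
                bbox_left=left,
                bbox_height=bottom - top + 1,
                bbox_width=right - left + 1,
                member_count=count,
            )
        )
    states[states == CANDIDATE] = CLUSTER
    return clusters


def classify_cluster(cluster: ClusterMatrix) -> ClusterKind:
    """Apply the singlet/doublet/noise size rules to a cluster's bbox.

    The doublet rule is orientation-symmetric (20×40 or 40×20): attached
    cell pairs have no preferred axis.
    """
    h, w = cluster.bbox_height, cluster.bbox_width
    if h <= SINGLET_MAX and w <= SINGLET_MAX:
        return ClusterKind.SINGLET
    if (h <= SINGLET_MAX and w <= DOUBLET_MAX) or (
        w <= SINGLET_MAX and h <= DOUBLET_MAX
    ):
        return ClusterKind.DOUBLET
    return ClusterKind.NOISE


def _floor_mid(start: int, length: int) -> int:
    # geometric center with ties broken toward the top-left
    return start + (length - 1) // 2


def _doublet_detections(cluster: ClusterMatrix) -> list[CellDetection]:
    """Two overlapping 20-px boxes tiled along the long axis.

    Centers sit at long-axis offsets ⌊L/4⌋ and ⌊3L/4⌋ (the midpoints of the
    two half-boxes), cross-axis at the floor midpoint.
    """
    horizontal = cluster.bbox_width > cluster.bbox_height
    if horizontal:
        long_len, long_start = cluster.bbox_width, cluster.bbox_left
        cross = _floor_mid(cluster.bbox_top, cluster.bbox_height)
    else:
        long_len, long_start = cluster.bbox_height, cluster.bbox_top
        cross = _floor_mid(cluster.bbox_left, cluster.bbox_width)
    box = min(SINGLET_MAX, long_len)
    starts = (long_start, long_start + long_len - box)
    offsets = (long_start + long_len // 4, long_start + (3 * long_len) // 4)
    detections = []
    for box_start, center_long in zip(starts, offsets):
        if horizontal:
            detections.append(
                CellDetection(
                    center_row=cross,
                    center_col=center_long,
                    bbox_top=cluster.bbox_top,
                    bbox_left=box_start,
                    bbox_height=cluster.bbox_height,
                    bbox_width=box,
                )
            )
        else:
            detections.append(
                CellDetection(
                    center_row=center_long,
                    center_col=cross,
                    bbox_top=box_start,
                    bbox_left=cluster.bbox_left,
                    bbox_height=box,
                    bbox_width=cluster.bbox_width,
                )
            )
    return detections


def mark_centers(
    plane: LabelPlane, clusters: list[ClusterMatrix]
) -> tuple[LabelPlane, list[CellDetection]]:
    """Produce the final center plane (60 on 255) and the detection list.

    Singlets yield one center at the bbox floor midpoint; doublets yield two
    (see :func:`_doublet_detections`); noise yields none.  The detection count
    equals the number of CENTER pixels in the returned plane.
    """
    final = LabelPlane(np.full(plane.shape, BACKGROUND, dtype=np.uint8))
    detections: list[CellDetection] = []
    for cluster in clusters:
        kind = classify_cluster(cluster)
        if kind is ClusterKind.SINGLET:
            detections.append(
                CellDetection(
                    center_row=_floor_mid(cluster.bbox_top, cluster.bbox_height),
                    center_col=_floor_mid(cluster.bbox_left, cluster.bbox_width),
                    bbox_top=cluster.bbox_top,
                    bbox_left=cluster.bbox_left,
                    bbox_height=cluster.bbox_height,
                    bbox_width=cluster.bbox_width,
                )
            )
        elif kind is ClusterKind.DOUBLET:
            detections.extend(_doublet_detections(cluster))
    for det in detections:
        final.states[det.center_row, det.center_col] = CENTER
    return final, detections


def count_cells(detections: list[CellDetection]) -> int:
    """Number of detected cells (= number of CENTER pixels in the plane)."""
    return len(detections)
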