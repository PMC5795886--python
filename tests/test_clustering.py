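import numpy as np
import pytest
from scipy import ndimage

from shadowcell import (
    BACKGROUND,
    CANDIDATE,
    CENTER,
    CLUSTER,
    ClusterKind,
    ClusterMatrix,
    LabelPlane,
    classify_cluster,
    count_cells,
    grow_clusters,
    mark_centers,
)

EIGHT = np.ones((3, 3), dtype=int)


def plane_from_mask(mask):
    return LabelPlane(np.where(mask, CANDIDATE, BACKGROUND).astype(np.uint8))


def rect_mask(shape, top, left, h, w):
    mask = np.zeros(shape, dtype=bool)
    mask[top : top + h, left : left + w] = True
    return mask


def components_in_raster_order(mask):
    """Independent oracle: 8-connected components, ordered by first raster pixel."""
    labels, n = ndimage.label(mask, structure=EIGHT)
    order = []
    seen = set()
    for v in labels.ravel().tolist():
        if v and v not in seen:
            seen.add(v)
            order.append(v)
    out = []
    for v in order:
        rows, cols = np.where(labels == v)
        out.append(
            (rows.min(), cols.min(), rows.max() - rows.min() + 1,
             cols.max() - cols.min() + 1, len(rows))
        )
    return out


class TestGrowClusters:
    def test_isolated_pixel(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[4, 4] = True
        clusters = grow_clusters(plane_from_mask(mask))
        assert len(clusters) == 1
        c = clusters[0]
        assert (c.bbox_height, c.bbox_width, c.member_count) == (1, 1, 1)

    def test_two_pixels_within_one_window(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[4, 4] = mask[5, 5] = True  # Chebyshev distance 1
        clusters = grow_clusters(plane_from_mask(mask))
        assert len(clusters) == 1
        assert clusters[0].member_count == 2

    def test_empty_plane(self):
        assert grow_clusters(plane_from_mask(np.zeros((5, 5), dtype=bool))) == []

    def test_absorbed_pixels_relabeled(self, rng):
        mask = rng.random((64, 64)) < 0.05
        plane = plane_from_mask(mask)
        grow_clusters(plane)
        assert not np.any(plane.states == CANDIDATE)
        assert (plane.states == CLUSTER).sum() == mask.sum()

    @pytest.mark.parametrize("density", [0.02, 0.1, 0.3])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_connected_component_oracle(self, density, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((128, 128)) < density
        clusters = grow_clusters(plane_from_mask(mask))
        ours = [
            (c.bbox_top, c.bbox_left, c.bbox_height, c.bbox_width, c.member_count)
            for c in clusters
        ]
        assert ours == components_in_raster_order(mask)

    def test_deterministic(self, rng):
        mask = rng.random((64, 64)) < 0.1
        a = grow_clusters(plane_from_mask(mask))
        b = grow_clusters(plane_from_mask(mask))
        assert a == b


class TestClassifyCluster:
    @pytest.mark.parametrize(
        "h,w,expected",
        [
            (18, 15, ClusterKind.SINGLET),
            (20, 20, ClusterKind.SINGLET),
            (1, 1, ClusterKind.SINGLET),
            (18, 36, ClusterKind.DOUBLET),
            (36, 18, ClusterKind.DOUBLET),
            (20, 40, ClusterKind.DOUBLET),
            (21, 21, ClusterKind.NOISE),
            (30, 30, ClusterKind.NOISE),
            (20, 41, ClusterKind.NOISE),
            (41, 20, ClusterKind.NOISE),
        ],
    )
    def test_size_rules(self, h, w, expected):
        cluster = ClusterMatrix(0, 0, h, w, member_count=h * w)
        assert classify_cluster(cluster) is expected


class TestMarkCenters:
    def test_singlet_center_floor_midpoint(self):
        # bbox rows 10–18, cols 20–28 (9×9) → center (14, 24)
        mask = rect_mask((40, 40), 10, 20, 9, 9)
        plane = plane_from_mask(mask)
        clusters = grow_clusters(plane)
        final, dets = mark_centers(plane, clusters)
        assert len(dets) == 1
        assert (dets[0].center_row, dets[0].center_col) == (14, 24)
        assert final.states[14, 24] == CENTER
        assert set(np.unique(final.states)) <= {CENTER, BACKGROUND}

    def test_doublet_quarter_point_centers(self):
        # 18×36 cluster at the origin → centers at col offsets ⌊36/4⌋ and ⌊3·36/4⌋
        mask = rect_mask((50, 50), 0, 0, 18, 36)
        plane = plane_from_mask(mask)
        final, dets = mark_centers(plane, grow_clusters(plane))
        assert [(d.center_row, d.center_col) for d in dets] == [(8, 9), (8, 27)]
        # each center lies inside its assigned 20-px half box
        for d in dets:
            assert d.bbox_left <= d.center_col < d.bbox_left + d.bbox_width
            assert d.bbox_width == 20
        assert (final.states == CENTER).sum() == 2

    def test_doublet_vertical_orientation(self):
        mask = rect_mask((50, 50), 0, 5, 36, 18)
        plane = plane_from_mask(mask)
        _, dets = mark_centers(plane, grow_clusters(plane))
        assert [(d.center_row, d.center_col) for d in dets] == [(9, 13), (27, 13)]

    def test_noise_yields_nothing(self):
        mask = rect_mask((60, 60), 5, 5, 30, 30)
        plane = plane_from_mask(mask)
        final, dets = mark_centers(plane, grow_clusters(plane))
        assert dets == []
        assert np.all(final.states == BACKGROUND)

    def test_count_matches_center_pixel_census(self, rng):
        mask = rng.random((128, 128)) < 0.02
        plane = plane_from_mask(mask)
        final, dets = mark_centers(plane, grow_clusters(plane))
        assert count_cells(dets) == (final.states == CENTER).sum()


class TestCounting:
    def test_empty(self):
        assert count_cells([]) == 0

    def test_singlet_plus_doublet_yields_three(self):
        mask = rect_mask((80, 80), 5, 5, 9, 9) | rect_mask((80, 80), 40, 30, 18, 36)
        plane = plane_from_mask(mask)
        _, dets = mark_centers(plane, grow_clusters(plane))
        assert count_cells(dets) == 3

    def test_monotone_recall_for_added_separated_singlet(self):
        shape = (100, 100)
        base = rect_mask(shape, 10, 10, 8, 8) | rect_mask(shape, 40, 40, 5, 5)
        plane = plane_from_mask(base)
        _, dets = mark_centers(plane, grow_clusters(plane))
        extra = base | rect_mask(shape, 70, 70, 10, 10)  # ≥ 3 px from others
        plane2 = plane_from_mask(extra)
        _, dets2 = mark_centers(plane2, grow_clusters(plane2))
        assert count_cells(dets2) == count_cells(dets) + 1
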