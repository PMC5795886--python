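import numpy as np
import pytest

from shadowcell import (
    BinarizationConfig,
    CapacityError,
    ClusterKind,
    ObjectClass,
    SceneConfig,
    binarize_image,
    classify_cluster,
    generate_dilution_series,
    generate_scene,
    grow_clusters,
    render_shadow_patch,
    suggest_gray_offset,
)
from shadowcell.clustering import classify_cluster as _classify

SMALL = dict(image_height=256, image_width=256)


class TestRenderShadowPatch:
    def test_zero_amplitude_is_flat_background(self):
        patch = render_shadow_patch(10.0, amplitude=0.0, background=200.0)
        assert np.all(patch.pixels == 200)

    def test_peak_to_peak_equals_amplitude(self):
        patch = render_shadow_patch(10.0, amplitude=100.0, background=200.0)
        ptp = int(patch.pixels.max()) - int(patch.pixels.min())
        assert abs(ptp - 100) <= 1

    def test_dead_to_live_contrast_ratio(self):
        live = render_shadow_patch(12.0, amplitude=50.0, background=200.0)
        dead = render_shadow_patch(12.0, amplitude=50.0 * 3.54, background=200.0)
        ratio = (int(dead.pixels.max()) - int(dead.pixels.min())) / (
            int(live.pixels.max()) - int(live.pixels.min()))
        assert ratio == pytest.approx(3.54, abs=0.1)

    def test_central_dip_with_surrounding_bright_ring(self):
        patch = render_shadow_patch(14.0, amplitude=80.0, background=200.0)
        mid = patch.height // 2
        assert patch.pixels[mid, mid] == patch.pixels.min()  # zero-order extremum
        assert patch.pixels.max() > 200  # first-order counter-extremum ring

    def test_clipping_warns(self):
        with pytest.warns(UserWarning):
            render_shadow_patch(10.0, amplitude=250.0, background=30.0)

    def test_tiny_diameter_rejected(self):
        with pytest.raises(Exception):
            render_shadow_patch(1.0, amplitude=50.0, background=200.0)


class TestGenerateScene:
    def test_empty_scene_is_uniform_background(self):
        cfg = SceneConfig(**SMALL, noise_sd=0.0)
        image, manifest = generate_scene(cfg, 0, 0, seed=4, n_debris=0, n_clumps=0)
        assert np.all(image.pixels == 200)
        assert manifest.objects == []

    def test_seed_determinism(self):
        cfg = SceneConfig(**SMALL, debris_rate=5, clump_rate=1)
        a_img, a_man = generate_scene(cfg, 10, 10, seed=9)
        b_img, b_man = generate_scene(cfg, 10, 10, seed=9)
        assert np.array_equal(a_img.pixels, b_img.pixels)
        assert a_man.to_dict() == b_man.to_dict()

    def test_different_seeds_differ(self):
        cfg = SceneConfig(**SMALL)
        a, _ = generate_scene(cfg, 10, 10, seed=1)
        b, _ = generate_scene(cfg, 10, 10, seed=2)
        assert not np.array_equal(a.pixels, b.pixels)

    def test_manifest_counts_match_requests(self):
        cfg = SceneConfig(**SMALL)
        _, manifest = generate_scene(cfg, 7, 3, seed=5, n_debris=4, n_clumps=1)
        assert manifest.count(ObjectClass.LIVE) == 7
        assert manifest.count(ObjectClass.DEAD) == 3
        assert manifest.count(ObjectClass.DEBRIS) == 4
        assert manifest.count(ObjectClass.CLUMP) == 1
        assert manifest.n_cells == 10

    def test_capacity_error_reports_density(self):
        cfg = SceneConfig(image_height=64, image_width=64)
        with pytest.raises(CapacityError):
            generate_scene(cfg, 300, 0, seed=0)

    def test_clump_footprints_exceed_noise_threshold(self):
        cfg = SceneConfig(**SMALL, noise_sd=0.0)
        image, _ = generate_scene(cfg, 0, 0, seed=11, n_debris=0, n_clumps=3)
        plane = binarize_image(image, BinarizationConfig(suggest_gray_offset(cfg)))
        clusters = grow_clusters(plane)
        assert len(clusters) == 3
        assert all(classify_cluster(c) is ClusterKind.NOISE for c in clusters)

    def test_debris_rejected_by_determination_value(self):
        cfg = SceneConfig(**SMALL, noise_sd=0.0)
        image, _ = generate_scene(cfg, 0, 0, seed=13, n_debris=15, n_clumps=0)
        plane = binarize_image(image, BinarizationConfig(suggest_gray_offset(cfg)))
        assert grow_clusters(plane) == []

    def test_cell_footprints_fit_singlet_regime(self):
        cfg = SceneConfig(**SMALL, noise_sd=0.0)
        image, manifest = generate_scene(cfg, 6, 6, seed=17)
        plane = binarize_image(image, BinarizationConfig(suggest_gray_offset(cfg)))
        clusters = grow_clusters(plane)
        assert len(clusters) == 12
        assert all(_classify(c) is ClusterKind.SINGLET for c in clusters)


class TestDilutionSeries:
    def test_degenerate_series(self):
        cfg = SceneConfig(**SMALL, cell_diameter_um=(10.0, 10.0))
        scenes = generate_dilution_series(cfg, [8e5], replicates=1, seed=3)
        assert len(scenes) == 1
        _, manifest = scenes[0]
        expected = 8e5 * cfg.fov_area_mm2 * 0.1 / 1000.0
        assert manifest.n_cells == round(expected)
        assert manifest.nominal_concentration == 8e5

    def test_monotone_mean_counts(self):
        cfg = SceneConfig(**SMALL, cell_diameter_um=(10.0, 10.0))
        scenes = generate_dilution_series(
            cfg, [2e5, 4e5, 8e5, 1.6e6], replicates=3, seed=1)
        assert len(scenes) == 12
        means = [
            np.mean([m.n_cells for _, m in scenes[3 * i : 3 * i + 3]])
            for i in range(4)
        ]
        assert means == sorted(means)
        assert means[0] < means[-1]

    def test_replicates_reproducible_from_master_seed(self):
        cfg = SceneConfig(**SMALL, cell_diameter_um=(10.0, 10.0))
        a = generate_dilution_series(cfg, [4e5], replicates=2, seed=42)
        b = generate_dilution_series(cfg, [4e5], replicates=2, seed=42)
        for (ia, ma), (ib, mb) in zip(a, b):
            assert np.array_equal(ia.pixels, ib.pixels)
            assert ma.to_dict() == mb.to_dict()

    def test_poisson_mode_varies_counts(self):
        cfg = SceneConfig(**SMALL, cell_diameter_um=(10.0, 10.0))
        scenes = generate_dilution_series(
            cfg, [8e5], replicates=6, seed=2, count_mode="poisson")
        counts = [m.n_cells for _, m in scenes]
        assert len(set(counts)) > 1

    def test_vanishing_concentration_warns(self):
        cfg = SceneConfig(**SMALL, cell_diameter_um=(10.0, 10.0))
        with pytest.warns(UserWarning):
            generate_dilution_series(cfg, [1e3], replicates=1, seed=0)
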