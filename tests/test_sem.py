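"""Image analysis: thresholding, classification, densities."""

import math

import numpy as np
import pytest

from rsacap import (
    CountMode,
    ImageRecord,
    analyze_image,
    calibrate_scale,
    default_scenario,
    detect_particles,
    generate_sem_image,
    histogram_threshold,
    normalized_profile_auc,
    particle_density,
    surface_mass_density,
)

IA_MASS = 5.26e-7


def disk_mask(shape, centers, radius):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    mask = np.zeros(shape, dtype=bool)
    for cx, cy in centers:
        mask |= (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
    return mask


class TestCalibration:
    def test_ratio(self):
        assert calibrate_scale(250.0, 500.0) == pytest.approx(2.0)

    def test_zero_bar_rejected(self):
        with pytest.raises(ValueError):
            calibrate_scale(0.0, 500.0)

    def test_generator_scale_bar_round_trip(self):
        sc = default_scenario(seed=4, image_shape=(256, 256), nm_per_px=4.0)
        img, truth = generate_sem_image(sc, 0.0, embed_scale_bar=True,
                                        scale_bar_nm=500.0)
        r0, c0, r1, c1 = img.scale_bar_bbox
        bar = img.pixels[r0:r1, c0:c1] == 255
        bar_px = bar.any(axis=0).sum()
        assert calibrate_scale(bar_px, truth["scale_bar_nm"]) == \
            pytest.approx(sc.nm_per_px, rel=0.05)


class TestThreshold:
    def test_separable_two_level_histogram(self):
        im = np.full((100, 100), 30, np.uint8)
        im[:20, :20] = 220
        t = histogram_threshold(im)
        assert 30 < t < 220

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            histogram_threshold(np.full((50, 50), 7, np.uint8))

    def test_synthetic_fixture_pixel_recovery(self):
        sc = default_scenario(seed=1, image_shape=(512, 512), nm_per_px=4.0)
        img, truth = generate_sem_image(sc, 0.05, embed_scale_bar=False)
        t = histogram_threshold(img.pixels)
        mask = img.pixels > t
        h, w = img.pixels.shape
        yy, xx = np.mgrid[0:h, 0:w]
        r = truth["diameter_px"] / 2
        core = np.zeros((h, w), bool)
        halo = np.zeros((h, w), bool)
        for cx, cy in truth["centers_px"]:
            d2 = (xx + 0.5 - cx) ** 2 + (yy + 0.5 - cy) ** 2
            core |= d2 < (r - 1) ** 2
            halo |= d2 < (r + 3) ** 2
        assert mask[core].mean() >= 0.99
        assert mask[~halo].mean() <= 0.01

    def test_invariant_under_brightness_offset(self):
        sc = default_scenario(seed=2, image_shape=(384, 384), nm_per_px=4.0)
        img, truth = generate_sem_image(sc, 0.05, embed_scale_bar=False)
        res0 = analyze_image(img, sc.particle.diameter_eff, mode="detached")
        shifted = ImageRecord((img.pixels.astype(int) + 20).clip(0, 255)
                              .astype(np.uint8), img.nm_per_px)
        res1 = analyze_image(shifted, sc.particle.diameter_eff,
                             mode="detached")
        assert res1.particles_total == res0.particles_total
        assert res1.threshold_used == res0.threshold_used + 20


class TestDetection:
    def test_planted_singles_counted_exactly(self):
        r = 10
        centers = [(30 + 70 * i, 30 + 70 * j)
                   for i in range(8) for j in range(7)][:50]
        mask = disk_mask((520, 600), centers, r)
        res = detect_particles(mask, expected_diameter_px=2 * r,
                               mode="detached")
        assert res.n_singles == 50
        assert res.particles_total == 50

    def test_empty_mask(self):
        res = detect_particles(np.zeros((64, 64), bool), 10.0)
        assert res.particles_total == 0

    def test_cluster_of_three_rule(self):
        # one blob of area ~3*A1 in detached mode counts as exactly 3
        r = 12
        centers = [(60, 60), (60 + 2 * r, 60), (60 + r, 60 + int(1.73 * r))]
        mask = disk_mask((160, 160), centers, r)
        res = detect_particles(mask, expected_diameter_px=2 * r,
                               mode="detached")
        assert res.n_small_clusters == 1
        assert res.particles_total == 3

    def test_clustered_mode_area_division(self):
        r = 10
        # chain of 5 overlapping disks: area ~ 5*A1 within rounding
        centers = [(40 + int(1.9 * r) * k, 60) for k in range(5)]
        mask = disk_mask((120, 260), centers, r)
        res = detect_particles(mask, expected_diameter_px=2 * r,
                               mode="clustered", self_calibrate=False)
        assert res.particles_total == pytest.approx(5, abs=1)

    def test_noise_blobs_discarded(self):
        mask = np.zeros((100, 100), bool)
        mask[10:13, 10:13] = True  # 9 px << 0.5 * A1 for d = 20
        res = detect_particles(mask, expected_diameter_px=20.0)
        assert res.particles_total == 0

    def test_small_expected_diameter_rejected(self):
        with pytest.raises(ValueError):
            detect_particles(np.zeros((10, 10), bool), 3.0)


class TestDensities:
    def test_density_unit_conversion(self):
        sc_img = ImageRecord(np.zeros((100, 100), np.uint8) + 1,
                             nm_per_px=100.0)  # field (0.01 mm)^2
        res = detect_particles(np.zeros((100, 100), bool), 10.0)
        res.particles_total = 100
        assert particle_density(res, sc_img) == pytest.approx(1e6)

    def test_surface_mass_density_back_chain(self):
        # Gamma = density * 100 * m reproduces the reference dry masses
        assert surface_mass_density(419 / (100 * IA_MASS), IA_MASS) == \
            pytest.approx(419.0)
        assert surface_mass_density(3.59e7, IA_MASS) == pytest.approx(
            1890.0, rel=5e-3)
        assert surface_mass_density(0.0, IA_MASS) == 0.0

    def test_noiseless_chain_is_exact(self):
        r = 10
        centers = [(40 + 60 * i, 40 + 60 * j)
                   for i in range(4) for j in range(4)]
        mask = disk_mask((260, 260), centers, r)
        img = ImageRecord((mask * 200).astype(np.uint8), nm_per_px=5.0)
        res = detect_particles(mask, 2 * r, mode="detached")
        dens = particle_density(res, img)
        gamma = surface_mass_density(dens, IA_MASS)
        expected = len(centers) * IA_MASS / img.field_area_mm2 * 100
        assert gamma == pytest.approx(expected, rel=1e-12)

    def test_unphysical_density_rejected(self):
        from rsacap.sem import check_physical_density

        d = 110.0
        a_mm2 = math.pi * (d * 1e-6 / 2) ** 2
        check_physical_density(0.9 / a_mm2, d)  # below hexagonal bound: ok
        with pytest.raises(RuntimeError):
            check_physical_density(0.95 / a_mm2, d)


class TestOverlay:
    def test_annotations_mark_singles_and_clusters(self):
        from rsacap.sem import annotate_overlay

        r = 10
        singles = [(40, 40), (40, 110)]
        cluster = [(120, 60), (120 + 2 * r, 60),
                   (120 + r, 60 + int(1.73 * r))]
        mask = disk_mask((200, 200), singles + cluster, r)
        img = ImageRecord((mask * 200).astype(np.uint8), nm_per_px=5.0)
        res = detect_particles(mask, 2 * r, mode="detached")
        rgb = annotate_overlay(img, res)
        assert rgb.shape == (200, 200, 3)
        # blue cross at each single centroid
        for cx, cy in singles:
            assert tuple(rgb[cy, cx]) == (60, 90, 255)
        # red outline around the cluster bounding box
        r0, c0, r1, c1 = res.cluster_bboxes[0]
        assert tuple(rgb[max(r0 - 1, 0), c0]) == (255, 60, 60)


class TestProfileAUC:
    def test_constant_profile(self):
        auc = normalized_profile_auc(np.ones(11), dx=400.0)
        assert auc == pytest.approx(10 * 400.0)

    def test_triangle_half_rectangle(self):
        tri = np.concatenate([np.linspace(0, 1, 6), np.linspace(1, 0, 6)[1:]])
        rect = np.ones_like(tri)
        assert normalized_profile_auc(tri, 400.0) == pytest.approx(
            normalized_profile_auc(rect, 400.0) / 2)

    def test_depth_ordering(self):
        x = np.arange(50.0)
        deep = np.exp(-x / 20.0)
        shallow = np.exp(-x / 5.0)
        assert normalized_profile_auc(deep) > normalized_profile_auc(shallow)

    def test_zero_profile_rejected(self):
        with pytest.raises(ValueError):
            normalized_profile_auc(np.zeros(5))


class TestEndToEndCounting:
    def test_detached_recovery(self, small_image_scenario):
        img, truth = generate_sem_image(small_image_scenario, 0.076)
        res = analyze_image(img, small_image_scenario.particle.diameter_eff,
                            mode="detached")
        err = abs(res.particles_total - truth["n_particles"]) \
            / truth["n_particles"]
        assert err <= 0.05

    def test_auto_mode_picks_clustered_for_clustered_image(self):
        sc = default_scenario(seed=8, image_shape=(768, 1024), nm_per_px=4.0)
        img, truth = generate_sem_image(sc, 0.30, cluster_fraction=0.8)
        res = analyze_image(img, sc.particle.diameter_eff, mode="auto")
        assert res.mode == CountMode.clustered
        err = abs(res.particles_total - truth["n_particles"]) \
            / truth["n_particles"]
        assert err <= 0.10
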