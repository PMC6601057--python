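"""Segmentation and enhancement operator contracts."""

import numpy as np
import pytest
from skimage.filters import threshold_otsu

from wsgrade.preprocess import (MeatMask, SegmentationError,
                                UnfillableRegionError, clahe, clean_mask,
                                fill_bright_holes, normalize_illumination,
                                otsu_threshold, overlay_blend,
                                preprocess_pipeline, remove_bright_pixels,
                                segment_background, PIPELINE_STAGES)
from wsgrade.synthetic import (SceneParams, degree_to_params, ellipse_mask,
                               render_scene)


class TestOtsu:
    def test_single_occupied_bin_returns_that_bin(self):
        h = np.zeros(256)
        h[113] = 500
        assert otsu_threshold(h) == 113

    def test_bimodal_split_falls_strictly_between_modes(self):
        h = np.zeros(256)
        h[50] = h[200] = 100
        assert 50 < otsu_threshold(h) < 200

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        h = rng.integers(0, 50, 256).astype(float)
        assert otsu_threshold(h) == otsu_threshold(h * 10)

    def test_matches_skimage_on_random_bimodal_histograms(self):
        # independent cross-check; skimage returns the last bin of the lower
        # class, this implementation the first bin of the upper class
        rng = np.random.default_rng(1)
        for _ in range(20):
            img = np.concatenate([
                rng.normal(80, 10, 500), rng.normal(180, 10, 500)
            ]).clip(0, 255).astype(np.uint8)
            h = np.bincount(img, minlength=256)
            assert abs(otsu_threshold(h) - threshold_otsu(hist=h)) <= 1

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.zeros(256))


class TestSegmentBackground:
    def test_recovers_rendered_ellipse(self):
        p = degree_to_params("MOD", 2)
        im = render_scene(p)
        gt = ellipse_mask(p)
        mask = segment_background(im.pixels).mask
        assert (mask & gt).sum() / gt.sum() >= 0.95

    def test_background_leakage_small(self):
        p = degree_to_params("NORM", 3)
        im = render_scene(p)
        gt = ellipse_mask(p)
        mask = clean_mask(remove_bright_pixels(
            im.pixels, segment_background(im.pixels))).mask
        assert (mask & ~gt).sum() / (~gt).sum() <= 0.01

    def test_all_blue_image_has_no_foreground(self):
        img = np.zeros((64, 64, 3), dtype=np.uint8)
        img[:] = (40, 70, 160)
        with pytest.raises(SegmentationError, match="no foreground"):
            segment_background(img)


class TestRemoveBrightPixels:
    def test_spotless_scene_nearly_unchanged(self):
        p = SceneParams(stripe_count=0, n_specular_spots=0, degree="NORM",
                        seed=7)
        im = render_scene(p)
        before = segment_background(im.pixels)
        after = remove_bright_pixels(im.pixels, before)
        inside = before.mask & ellipse_mask(p)
        removed = inside & ~after.mask
        assert removed.sum() / inside.sum() <= 0.01

    def test_saturated_spot_fully_removed(self):
        img = np.full((32, 32, 3), (180, 120, 130), dtype=np.uint8)
        img[10:14, 10:14] = 255
        mask = MeatMask(np.ones((32, 32), dtype=bool))
        out = remove_bright_pixels(img, mask)
        assert not out.mask[10:14, 10:14].any()

    def test_uniform_region_untouched(self):
        img = np.full((16, 16, 3), (180, 120, 130), dtype=np.uint8)
        mask = MeatMask(np.ones((16, 16), dtype=bool))
        assert remove_bright_pixels(img, mask).mask.all()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            remove_bright_pixels(np.zeros((4, 4, 3), dtype=np.uint8),
                                 MeatMask(np.zeros((4, 4), dtype=bool)))


class TestCleanMask:
    def test_speckles_removed_ellipse_kept(self):
        m = np.zeros((100, 100), dtype=bool)
        yy, xx = np.mgrid[0:100, 0:100]
        m[((yy - 50) / 30) ** 2 + ((xx - 50) / 20) ** 2 <= 1] = True
        rng = np.random.default_rng(0)
        speckles = np.zeros_like(m)
        for _ in range(10):
            r, c = rng.integers(0, 95, 2)
            if not m[r:r + 3, c:c + 3].any():
                speckles[r:r + 2, c:c + 2] = True
        cleaned = clean_mask(MeatMask(m | speckles)).mask
        assert (cleaned == m).all()

    def test_single_component_identity(self):
        m = np.zeros((50, 50), dtype=bool)
        m[10:40, 10:40] = True
        assert (clean_mask(MeatMask(m)).mask == m).all()

    def test_threshold_is_inclusive(self):
        # components of 100 and 99 px with a 100 px cutoff (0.04 of 50x50)
        m = np.zeros((50, 50), dtype=bool)
        m[0:10, 0:10] = True            # 100 px
        m[30:39, 30:41] = True          # 99 px
        cleaned = clean_mask(MeatMask(m), min_area_fraction=100 / 2500)
        assert cleaned.mask[0:10, 0:10].all()
        assert not cleaned.mask[30:39, 30:41].any()

    def test_largest_retained_when_all_small(self):
        m = np.zeros((50, 50), dtype=bool)
        m[0:3, 0:3] = True
        m[10:12, 10:12] = True
        cleaned = clean_mask(MeatMask(m), min_area_fraction=0.5)
        assert cleaned.mask.sum() == 9

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        m = rng.random((60, 60)) < 0.45
        once = clean_mask(MeatMask(m)).mask
        twice = clean_mask(MeatMask(once)).mask
        assert (once == twice).all()


class TestOverlayBlend:
    def test_fixed_points_and_mid_identity_full_grid(self):
        I, M = np.meshgrid(np.arange(256.0), np.arange(256.0), indexing="ij")
        E = overlay_blend(I, M)
        assert (E[0, :] == 0).all()
        assert (E[255, :] == 255).all()
        assert overlay_blend(np.array(128.0), np.array(127.5)) == 128.0

    def test_derived_value(self):
        # (64/255)*(64 + 2*1*(255-64)) = 111.9372...
        E = overlay_blend(np.array(64.0), np.array(255.0))
        assert E == pytest.approx(64 / 255 * (64 + 2 * 191), abs=1e-9)
        assert E == pytest.approx(111.94, abs=0.01)

    def test_monotone_in_lightness_for_every_base(self):
        I, M = np.meshgrid(np.arange(256.0), np.arange(256.0), indexing="ij")
        E = overlay_blend(I, M)
        assert (np.diff(E, axis=1) >= 0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            overlay_blend(np.array(300.0), np.array(10.0))


class TestNormalizeIllumination:
    def test_uniform_image_stays_uniform(self):
        img = np.full((40, 40, 3), 90, dtype=np.uint8)
        out = normalize_illumination(img)
        assert np.allclose(out, out[0, 0], atol=1e-6)

    def test_bright_spot_attenuated(self):
        img = np.full((64, 64, 3), 100.0)
        yy, xx = np.mgrid[0:64, 0:64]
        spot = 120.0 * np.exp(-(((yy - 32) ** 2 + (xx - 32) ** 2) / 50.0))
        img += spot[..., None]
        out = normalize_illumination(np.clip(img, 0, 255))
        assert out[32, 32].mean() < img[32, 32].mean()

    def test_output_in_range(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, (32, 32, 3)).astype(np.uint8)
        out = normalize_illumination(img)
        assert out.min() >= 0 and out.max() <= 255


class TestFillBrightHoles:
    def test_no_holes_identity(self):
        g = np.full((20, 20), 77, dtype=np.uint8)
        mask = MeatMask(np.ones((20, 20), dtype=bool))
        assert (fill_bright_holes(g, mask) == g).all()

    def test_single_hole_neighborhood_mean(self):
        g = np.full((21, 21), 100, dtype=np.uint8)
        g[10, 10] = 0
        out = fill_bright_holes(g, MeatMask(np.ones((21, 21), dtype=bool)))
        assert out[10, 10] == 100

    def test_3x3_hole_in_constant_region(self):
        g = np.full((31, 31), 128, dtype=np.uint8)
        g[14:17, 14:17] = 0
        out = fill_bright_holes(g, MeatMask(np.ones((31, 31), dtype=bool)),
                                window=25)
        assert (out == 128).all()

    def test_never_modifies_nonzero_pixels(self):
        rng = np.random.default_rng(5)
        g = rng.integers(1, 256, (30, 30)).astype(np.uint8)
        holes = rng.random((30, 30)) < 0.2
        g[holes] = 0
        mask = MeatMask(np.ones((30, 30), dtype=bool))
        out = fill_bright_holes(g, mask)
        assert (out[~holes] == g[~holes]).all()
        assert (out[holes] > 0).all()

    def test_unfillable_all_zero(self):
        g = np.zeros((10, 10), dtype=np.uint8)
        with pytest.raises(UnfillableRegionError):
            fill_bright_holes(g, MeatMask(np.ones((10, 10), dtype=bool)),
                              window=3)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            fill_bright_holes(np.ones((5, 5), dtype=np.uint8),
                              MeatMask(np.ones((5, 5), dtype=bool)), window=4)


class TestClahe:
    def test_constant_image_stays_constant(self):
        g = np.full((64, 64), 120, dtype=np.uint8)
        out = clahe(g, MeatMask(np.ones((64, 64), dtype=bool)))
        assert len(np.unique(out)) == 1

    def test_contrast_not_reduced_on_striped_region(self):
        p = degree_to_params("SEV", 4)
        im = render_scene(p)
        from wsgrade.preprocess import to_gray
        g = np.clip(np.rint(to_gray(im.pixels)), 1, 255).astype(np.uint8)
        mask = MeatMask(ellipse_mask(p))
        g = np.where(mask.mask, g, 0).astype(np.uint8)
        out = clahe(g, mask)
        assert out[mask.mask].std() >= g[mask.mask].std()

    def test_invalid_clip_rejected(self):
        with pytest.raises(ValueError):
            clahe(np.ones((8, 8), dtype=np.uint8),
                  MeatMask(np.ones((8, 8), dtype=bool)), clip_limit=0.0)


class TestPipeline:
    def test_end_to_end_on_sev_scene(self):
        p = degree_to_params("SEV", 6)
        enh = preprocess_pipeline(render_scene(p).pixels)
        assert enh.mask.meat_area > 0
        holes = (enh.gray == 0) & enh.mask.mask
        assert holes.sum() == 0
        assert enh.provenance == list(PIPELINE_STAGES)

    def test_all_background_fails_at_segmentation(self):
        img = np.zeros((64, 64, 3), dtype=np.uint8)
        img[:] = (40, 70, 160)
        with pytest.raises(SegmentationError, match="no foreground"):
            preprocess_pipeline(img)

    def test_exterior_is_zero(self):
        p = degree_to_params("NORM", 8)
        enh = preprocess_pipeline(render_scene(p).pixels)
        assert (enh.gray[~enh.mask.mask] == 0).all()
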