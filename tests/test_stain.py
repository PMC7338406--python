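import numpy as np
import pytest

from skie.core import PipelineConfig, RasterImage
from skie.stain import (
    BinaryMask,
    StainMatrix,
    color_deconvolve,
    component_centroids,
    downscale,
    ki67_in_tumor,
    mask_components,
    od_to_rgb,
    reconstruct_od,
    rgb_to_od,
    segment_ki67,
    segment_synaptophysin,
)

CFG = PipelineConfig()
M_DS = StainMatrix.ds_default(CFG)


def _image_from_concentrations(conc: np.ndarray, M: StainMatrix) -> RasterImage:
    od = reconstruct_od(conc, M)
    return RasterImage(od_to_rgb(od), mpp=2.0)


class TestOpticalDensity:
    def test_white_has_no_absorption(self):
        od = rgb_to_od(np.full((2, 2, 3), 255, dtype=np.uint8))
        assert np.allclose(od, -np.log10(256 / 255), atol=1e-6)
        assert np.all(np.abs(od) < 0.01)

    def test_known_value(self):
        # I = 24 -> OD = -log10(25/255)
        od = rgb_to_od(np.full((1, 1, 3), 24, dtype=np.uint8))
        assert od[0, 0, 0] == pytest.approx(-np.log10(25 / 255), abs=1e-6)

    def test_monotone_decreasing_in_intensity(self):
        ramp = np.arange(256, dtype=np.uint8).reshape(1, 256, 1).repeat(3, axis=2)
        od = rgb_to_od(ramp)[0, :, 0]
        assert np.all(np.diff(od) < 0)

    def test_od_rgb_roundtrip(self):
        rng = np.random.default_rng(0)
        rgb = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        assert np.array_equal(od_to_rgb(rgb_to_od(rgb)), rgb)


class TestColorDeconvolution:
    @pytest.mark.parametrize(
        "conc",
        [
            (0.8, 0.0, 0.0),  # pure hematoxylin
            (0.0, 0.5, 0.3),  # DAB + Permanent Red mixture
            (0.2, 0.2, 0.2),
        ],
    )
    def test_forward_model_inversion(self, conc):
        field = np.full((4, 4, 3), conc, dtype=float)
        od_true = reconstruct_od(field, M_DS)
        # bypass 8-bit quantisation: feed the exact OD through the inverse
        inv = np.linalg.inv(M_DS.matrix)
        rec = od_true.reshape(-1, 3) @ inv
        assert np.allclose(rec, np.asarray(conc), atol=1e-6)

    def test_quantised_pixels_recover_concentrations(self):
        img = _image_from_concentrations(np.full((4, 4, 3), (0.8, 0.0, 0.0)), M_DS)
        conc = color_deconvolve(img, M_DS)
        assert np.allclose(conc[..., 0], 0.8, atol=0.02)
        assert np.all(conc[..., 1:] < 0.02)

    def test_white_pixel_zero_concentration(self):
        img = RasterImage(np.full((2, 2, 3), 255, dtype=np.uint8), 1.0)
        conc = color_deconvolve(img, M_DS)
        assert np.all(np.abs(conc) < 0.02)

    def test_roundtrip_reconstruction_under_1e6(self):
        rng = np.random.default_rng(1)
        conc = rng.uniform(0, 1.0, (64, 3))
        od = conc @ M_DS.matrix
        rec = od @ np.linalg.inv(M_DS.matrix)
        assert np.max(np.abs(rec @ M_DS.matrix - od)) < 1e-6
        assert np.max(np.abs(rec - conc)) < 1e-6

    def test_singular_matrix_rejected(self):
        v = (0.5, 0.5, 0.7071)
        with pytest.raises(ValueError, match="singular"):
            StainMatrix(np.array([v, v, (0.1, 0.2, 0.97)]), ("a", "b", "c"))


class TestDownscale:
    def test_factor_one_is_identity(self):
        img = RasterImage(np.random.default_rng(0).integers(0, 256, (10, 10, 3), dtype=np.uint8), 0.5)
        assert downscale(img, 1) is img

    def test_shapes_and_mpp(self):
        img = RasterImage(np.zeros((1000, 1000, 3), dtype=np.uint8), 0.5)
        out = downscale(img, 4)
        assert out.shape == (250, 250)
        assert out.mpp == 2.0

    def test_constant_stays_constant(self):
        img = RasterImage(np.full((64, 64, 3), 113, dtype=np.uint8), 0.5)
        assert np.all(downscale(img, 4).pixels == 113)

    def test_errors(self):
        img = RasterImage(np.zeros((8, 8, 3), dtype=np.uint8), 0.5)
        with pytest.raises(ValueError):
            downscale(img, 16)
        with pytest.raises(ValueError):
            downscale(img, 0)


def _paint_disk(arr, r, c, radius, value):
    rr, cc = np.ogrid[: arr.shape[0], : arr.shape[1]]
    arr[(rr - r) ** 2 + (cc - c) ** 2 <= radius**2] = value


def _ds_like_image(n_brown=0, blob_specs=(), size=400, brown_positions=None):
    """Hand-built DS-style image: red elliptical blobs + brown disks."""
    conc = np.zeros((size, size, 3), dtype=float)  # hema, dab, red
    for (r, c, ar, ac) in blob_specs:
        rr, cc = np.ogrid[:size, :size]
        conc[..., 2][((rr - r) / ar) ** 2 + ((cc - c) / ac) ** 2 <= 1] = 0.4
    if brown_positions is None:
        rng = np.random.default_rng(0)
        brown_positions = []
        while len(brown_positions) < n_brown:
            p = rng.integers(20, size - 20, 2)
            if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 > 30**2 for q in brown_positions):
                brown_positions.append(tuple(p))
    dab = conc[..., 1]
    for (r, c) in brown_positions:
        _paint_disk(dab, r, c, 8, 0.85)
    return _image_from_concentrations(conc, M_DS), brown_positions


class TestSegmentation:
    def test_ki67_component_count_matches_planted(self):
        img, pos = _ds_like_image(n_brown=40, blob_specs=[(200, 200, 180, 180)])
        small = downscale(img, CFG.deconv_downscale)
        channels = color_deconvolve(small, M_DS)
        mask = segment_ki67(channels, M_DS, CFG)
        _, n = mask_components(mask)
        assert n == 40
        assert mask.provenance == "ki67"

    def test_no_dab_gives_empty_mask(self):
        img, _ = _ds_like_image(n_brown=0, blob_specs=[(200, 200, 150, 150)])
        channels = color_deconvolve(downscale(img, 4), M_DS)
        assert segment_ki67(channels, M_DS, CFG).area == 0

    def test_salt_noise_below_min_area_ignored(self):
        img, _ = _ds_like_image(n_brown=20, blob_specs=[(200, 200, 180, 180)])
        px = img.pixels.copy()
        rng = np.random.default_rng(5)
        # single-pixel brown salt: below the minimum object area at 1/4 scale
        for _ in range(50):
            r, c = rng.integers(0, px.shape[0], 2)
            px[r, c] = (90, 50, 20)
        noisy = RasterImage(px, img.mpp)
        ch_clean = color_deconvolve(downscale(img, 4), M_DS)
        ch_noisy = color_deconvolve(downscale(noisy, 4), M_DS)
        _, n_clean = mask_components(segment_ki67(ch_clean, M_DS, CFG))
        _, n_noisy = mask_components(segment_ki67(ch_noisy, M_DS, CFG))
        assert n_clean == n_noisy == 20

    def test_synaptophysin_blob_area_within_5pct(self):
        img, _ = _ds_like_image(n_brown=0, blob_specs=[(200, 200, 150, 160)])
        channels = color_deconvolve(downscale(img, 4), M_DS)
        mask = segment_synaptophysin(channels, M_DS, CFG)
        planted_area = np.pi * 150 * 160 / 16  # at 1/4 scale
        assert mask.area == pytest.approx(planted_area, rel=0.05)

    def test_two_disjoint_blobs_two_components(self):
        img, _ = _ds_like_image(n_brown=0, blob_specs=[(100, 100, 60, 60), (300, 300, 70, 50)])
        channels = color_deconvolve(downscale(img, 4), M_DS)
        mask = segment_synaptophysin(channels, M_DS, CFG)
        _, n = mask_components(mask)
        assert n == 2

    def test_no_red_gives_empty_mask(self):
        img, _ = _ds_like_image(n_brown=5)
        channels = color_deconvolve(downscale(img, 4), M_DS)
        assert segment_synaptophysin(channels, M_DS, CFG).area == 0

    def test_masks_invariant_to_faint_background_tint(self):
        img, _ = _ds_like_image(n_brown=15, blob_specs=[(200, 200, 170, 170)])
        conc_tint = np.full((400, 400, 3), (0.0, 0.04, 0.0))  # faint DAB wash below floor
        od = rgb_to_od(img.pixels) + reconstruct_od(conc_tint, M_DS)
        tinted = RasterImage(od_to_rgb(od), img.mpp)
        ch_a = color_deconvolve(downscale(img, 4), M_DS)
        ch_b = color_deconvolve(downscale(tinted, 4), M_DS)
        _, n_a = mask_components(segment_ki67(ch_a, M_DS, CFG))
        _, n_b = mask_components(segment_ki67(ch_b, M_DS, CFG))
        assert n_a == n_b == 15

    def test_intersection_mask(self):
        a = BinaryMask(np.array([[True, False], [True, True]]), "ki67", 4)
        b = BinaryMask(np.array([[True, True], [False, True]]), "synaptophysin", 4)
        both = ki67_in_tumor(a, b)
        assert both.provenance == "ki67_in_tumor"
        assert both.mask.tolist() == [[True, False], [False, True]]
        with pytest.raises(ValueError):
            ki67_in_tumor(a, BinaryMask(np.ones((3, 3), dtype=bool), "synaptophysin", 2))


class TestGeneratorIntegration:
    def test_ki67_mask_counts_positives_on_fixture(self, small_pair):
        he, ds, ss, truth = small_pair
        channels = color_deconvolve(downscale(ds, 4), M_DS)
        mask = segment_ki67(channels, M_DS, CFG)
        _, n = mask_components(mask)
        n_planted = int(truth.positive.sum())
        # clumped pairs of positives may merge; tolerate a small deficit
        assert abs(n - n_planted) <= max(2, 0.1 * n_planted)

    def test_tumor_mask_covers_blob(self, small_pair):
        he, ds, ss, truth = small_pair
        channels = color_deconvolve(downscale(ds, 4), M_DS)
        mask = segment_synaptophysin(channels, M_DS, CFG)
        blob = truth.blob_mask()[::4, ::4]
        iou = (mask.mask & blob).sum() / (mask.mask | blob).sum()
        assert iou > 0.9

    def test_centroids_scale_to_source_coordinates(self, small_pair):
        he, ds, ss, truth = small_pair
        channels = color_deconvolve(downscale(ds, 4), M_DS)
        mask = segment_ki67(channels, M_DS, CFG)
        cents = component_centroids(mask)
        assert len(cents) > 0
        assert cents[:, 0].max() <= ds.shape[0] and cents[:, 1].max() <= ds.shape[1]
        # each detected centroid is near some planted positive nucleus
        pos = truth.centers[truth.positive]
        d2 = ((cents[:, None, :] - pos[None, :, :]) ** 2).sum(-1).min(1)
        assert np.sqrt(d2).max() < 3 * truth.spec.nucleus_radius_px
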