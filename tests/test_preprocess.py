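"""Enhancement, resizing, normalization: oracles and invariants."""

import numpy as np
import pytest

from cardioseg.errors import ConfigError, RangeError, StructuralError
from cardioseg.phantom import PhantomParams, generate_slice
from cardioseg.preprocess import (EnhanceConfig, apply_bilateral, apply_clahe,
                                  enhance, histogram_report,
                                  interdecile_range, normalize, resize_pair)


# ---------------------------------------------------------------------------
# CLAHE
# ---------------------------------------------------------------------------

def clahe_reference(img8, clip_limit, tile_grid):
    """Brute-force per-pixel CLAHE: per-tile clipped CDF lookup tables,
    bilinear interpolation between the four surrounding tile centers."""
    rows, cols = tile_grid
    h, w = img8.shape
    ye = np.linspace(0, h, rows + 1).astype(int)
    xe = np.linspace(0, w, cols + 1).astype(int)
    luts = np.zeros((rows, cols, 256))
    for i in range(rows):
        for j in range(cols):
            tile = img8[ye[i]:ye[i + 1], xe[j]:xe[j + 1]]
            hist = np.bincount(tile.ravel(), minlength=256).astype(float)
            clip = max(clip_limit * tile.size / 256.0, 1.0)
            excess = np.clip(hist - clip, 0, None).sum()
            hist = np.minimum(hist, clip) + excess / 256.0
            luts[i, j] = np.cumsum(hist) * 255.0 / tile.size
    yc = (ye[:-1] + ye[1:]) / 2.0
    xc = (xe[:-1] + xe[1:]) / 2.0
    out = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            py = min(max(y, yc[0]), yc[-1])
            px = min(max(x, xc[0]), xc[-1])
            i1 = min(np.searchsorted(yc, py, side="right"), rows - 1)
            j1 = min(np.searchsorted(xc, px, side="right"), cols - 1)
            i1, j1 = max(i1, 1), max(j1, 1)
            i0, j0 = i1 - 1, j1 - 1
            fy = (py - yc[i0]) / (yc[i1] - yc[i0]) if rows > 1 else 0.0
            fx = (px - xc[j0]) / (xc[j1] - xc[j0]) if cols > 1 else 0.0
            v = img8[y, x]
            out[y, x] = ((1 - fy) * (1 - fx) * luts[i0, j0, v]
                         + (1 - fy) * fx * luts[i0, j1, v]
                         + fy * (1 - fx) * luts[i1, j0, v]
                         + fy * fx * luts[i1, j1, v])
    return np.clip(out, 0, 255)


class TestClahe:
    def test_constant_image_stays_constant(self):
        out = apply_clahe(np.full((32, 32), 128.0))
        assert np.allclose(out, out.ravel()[0])

    def test_matches_bruteforce_reference(self, rng):
        img = rng.integers(80, 170, (40, 48)).astype(np.float64)
        out = apply_clahe(img, clip_limit=2.0, tile_grid=(4, 4))
        ref = clahe_reference(img.astype(np.uint8), 2.0, (4, 4))
        np.testing.assert_allclose(out, ref, atol=1e-3)

    def test_raises_contrast_of_low_contrast_ramp(self):
        ramp = np.tile(np.linspace(100, 130, 64), (64, 1))
        out = apply_clahe(ramp, tile_grid=(8, 8))
        assert out.std() >= ramp.std()
        assert out.min() >= 0 and out.max() <= 255

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ConfigError):
            apply_clahe(np.zeros((16, 16)), tile_grid=(0, 8))
        with pytest.raises(ConfigError):
            apply_clahe(np.zeros((16, 16)), clip_limit=0.0)


# ---------------------------------------------------------------------------
# bilateral
# ---------------------------------------------------------------------------

def bilateral_reference(img, diameter, s_int, s_space):
    r = diameter // 2
    pad = np.pad(img.astype(float), r, mode="reflect")
    out = np.zeros_like(img, dtype=float)
    for y in range(img.shape[0]):
        for x in range(img.shape[1]):
            num = den = 0.0
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    v = pad[y + r + di, x + r + dj]
                    wgt = np.exp(-(di * di + dj * dj) / (2 * s_space ** 2)) \
                        * np.exp(-(v - img[y, x]) ** 2 / (2 * s_int ** 2))
                    num += wgt * v
                    den += wgt
            out[y, x] = num / den
    return out


class TestBilateral:
    def test_constant_image_unchanged(self):
        img = np.full((16, 16), 77.0)
        np.testing.assert_allclose(apply_bilateral(img), img, rtol=1e-6)

    def test_matches_bruteforce_kernel_sum(self, rng):
        img = rng.uniform(0, 255, (12, 14))
        out = apply_bilateral(img, 5, 30.0, 2.0)
        ref = bilateral_reference(img, 5, 30.0, 2.0)
        np.testing.assert_allclose(out, ref, rtol=1e-5, atol=1e-3)

    def test_denoises_flats_but_keeps_the_edge(self, rng):
        img = np.where(np.arange(40)[None, :] < 20, 50.0, 200.0)
        img = np.tile(img, (40, 1))
        noisy = img + rng.normal(0, 10, img.shape)
        out = apply_bilateral(noisy, 9, 30.0, 3.0)
        for sl in (np.s_[:, :15], np.s_[:, 25:]):
            assert out[sl].var() < noisy[sl].var()
        jump = out[:, 25:].mean() - out[:, :15].mean()
        assert jump >= 0.9 * 150
        assert out.min() >= noisy.min() and out.max() <= noisy.max()

    def test_isolated_bright_pixel_survives(self):
        img = np.zeros((15, 15))
        img[7, 7] = 200.0
        out = apply_bilateral(img, 7, 5.0, 10.0)
        assert abs(out[7, 7] - 200.0) / 200.0 < 0.01

    def test_even_diameter_rejected(self):
        with pytest.raises(ConfigError):
            apply_bilateral(np.zeros((8, 8)), diameter=4)


# ---------------------------------------------------------------------------
# composition / resize / normalize / histogram
# ---------------------------------------------------------------------------

class TestEnhance:
    def test_disabled_is_bit_identical(self, rng):
        img = rng.uniform(0, 255, (32, 32)).astype(np.float32)
        out = enhance(img, EnhanceConfig(enabled=False))
        assert np.array_equal(out, img)

    def test_equals_manual_stage_composition(self, rng):
        img = rng.uniform(0, 255, (32, 32))
        cfg = EnhanceConfig()
        manual = apply_bilateral(
            apply_clahe(img, cfg.clahe_clip_limit, cfg.clahe_tile_grid),
            cfg.bilateral_diameter, cfg.bilateral_sigma_intensity,
            cfg.bilateral_sigma_space)
        np.testing.assert_array_equal(enhance(img, cfg), manual)

    def test_spreads_phantom_histogram(self):
        img, _ = generate_slice(PhantomParams.for_size(64, seed=2), 0)
        out = enhance(img)
        assert interdecile_range(out) > interdecile_range(img)

    def test_enhance_is_deterministic(self):
        img, _ = generate_slice(PhantomParams.for_size(64, seed=2), 1)
        assert np.array_equal(enhance(img), enhance(img))


class TestResizePair:
    def test_identity_resize_preserves_mask(self, rng):
        img = rng.uniform(0, 255, (64, 64))
        mask = rng.integers(0, 3, (64, 64)).astype(np.uint8)
        img2, mask2 = resize_pair(img, mask, 64)
        assert np.array_equal(mask, mask2)

    def test_upsampled_mask_never_invents_labels(self, rng):
        mask = rng.integers(0, 3, (32, 32)).astype(np.uint8)
        _, up = resize_pair(rng.uniform(0, 255, (32, 32)), mask, 64)
        assert set(np.unique(up)) <= set(np.unique(mask))

    def test_area_scales_quadratically(self):
        mask = np.zeros((100, 100), np.uint8)
        yy, xx = np.mgrid[0:100, 0:100]
        mask[(yy - 50) ** 2 + (xx - 50) ** 2 <= 30 ** 2] = 1
        area = (mask == 1).sum()
        _, up = resize_pair(np.zeros((100, 100)), mask, 256)
        scaled = area * (256 / 100) ** 2
        assert abs(int((up == 1).sum()) - scaled) / scaled < 0.15

    def test_tiny_target_rejected(self):
        with pytest.raises(ConfigError):
            resize_pair(np.zeros((64, 64)), np.zeros((64, 64)), 16)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(StructuralError):
            resize_pair(np.zeros((64, 64)), np.zeros((32, 32)), 64)


class TestNormalize:
    def test_endpoints_and_arithmetic(self):
        img = np.array([[0.0, 255.0], [51.0, 127.5]])
        out = normalize(img)
        np.testing.assert_allclose(out, [[0.0, 1.0], [0.2, 0.5]], atol=1e-7)

    def test_linearity(self, rng):
        img = rng.uniform(0, 100, (8, 8))
        np.testing.assert_allclose(normalize(2.0 * img), 2.0 * normalize(img),
                                   rtol=1e-6)

    def test_out_of_range_rejected(self):
        with pytest.raises(RangeError):
            normalize(np.array([[0.0, 300.0]]))
        with pytest.raises(RangeError):
            normalize(np.array([[-1.0, 3.0]]))


class TestHistogramReport:
    def test_identical_images_identical_histograms(self, rng):
        img = rng.uniform(0, 255, (16, 16))
        rep = histogram_report(img, img)
        assert (rep.count_before == rep.count_after).all()

    def test_counts_are_conserved(self, rng):
        a = rng.uniform(0, 255, (20, 30))
        b = rng.uniform(0, 255, (20, 30))
        rep = histogram_report(a, b)
        assert rep.count_before.sum() == 600 == rep.count_after.sum()

    def test_full_ramp_fills_every_bin_equally(self):
        ramp = np.tile(np.arange(256), (256, 1))
        rep = histogram_report(ramp, ramp)
        assert (rep.count_before == 256).all()


def test_enhance_config_validation():
    with pytest.raises(ConfigError):
        EnhanceConfig(bilateral_diameter=8)
    with pytest.raises(ConfigError):
        EnhanceConfig(clahe_clip_limit=-1)
    with pytest.raises(ConfigError):
        EnhanceConfig(clahe_tile_grid=(0, 8))
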