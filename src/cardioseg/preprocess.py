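"""Dual-stage image enhancement and input standardization.

The enhancement is contrast-limited adaptive histogram equalization (CLAHE)
followed by a bilateral filter, in that fixed order: CLAHE raises local
contrast (and with it, noise); the bilateral stage then suppresses the noise
while preserving tissue borders.  Both stages are implemented here directly
(vectorized NumPy) with the conventional parameterization: the CLAHE clip
limit is a multiple of the mean histogram bin height per tile, and the
bilateral sigmas are in pixels (spatial) and intensity units (range).

After enhancement, images are resized to the network size (bilinear for
images, nearest-neighbor for masks so labels are never invented) and mapped
linearly from [0, 255] to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from .errors import ConfigError, RangeError, StructuralError


@dataclass
class EnhanceConfig:
    """Parameters of the CLAHE + bilateral enhancement stage.

    Defaults are the canonical ones for each filter; the clip limit and tile
    grid control how aggressively local contrast is raised, the bilateral
    sigmas how strongly noise is smoothed and how sharply edges are kept.
    """

    clahe_clip_limit: float = 2.0
    clahe_tile_grid: tuple[int, int] = (8, 8)
    bilateral_diameter: int = 9
    bilateral_sigma_intensity: float = 30.0
    bilateral_sigma_space: float = 75.0
    enabled: bool = True

    def __post_init__(self):
        if self.clahe_clip_limit <= 0:
            raise ConfigError("clahe_clip_limit must be positive")
        if min(self.clahe_tile_grid) < 1:
            raise ConfigError("clahe_tile_grid entries must be >= 1")
        if self.bilateral_diameter < 1 or self.bilateral_diameter % 2 == 0:
            raise ConfigError("bilateral_diameter must be odd and positive")
        if self.bilateral_sigma_intensity <= 0 or self.bilateral_sigma_space <= 0:
            raise ConfigError("bilateral sigmas must be positive")


# ---------------------------------------------------------------------------
# CLAHE
# ---------------------------------------------------------------------------

def _tile_luts(img8: np.ndarray, clip_limit: float,
               tile_grid: tuple[int, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-tile clipped-equalization lookup tables plus tile center coords."""
    rows, cols = tile_grid
    h, w = img8.shape
    y_edges = np.linspace(0, h, rows + 1).astype(int)
    x_edges = np.linspace(0, w, cols + 1).astype(int)
    luts = np.empty((rows, cols, 256), np.float64)
    for i in range(rows):
        for j in range(cols):
            tile = img8[y_edges[i]:y_edges[i + 1], x_edges[j]:x_edges[j + 1]]
            npix = tile.size
            hist = np.bincount(tile.ravel(), minlength=256).astype(np.float64)
            clip = max(clip_limit * npix / 256.0, 1.0)
            excess = np.clip(hist - clip, 0.0, None).sum()
            hist = np.minimum(hist, clip) + excess / 256.0
            cdf = np.cumsum(hist)
            luts[i, j] = cdf * (255.0 / npix)
    yc = (y_edges[:-1] + y_edges[1:]) / 2.0
    xc = (x_edges[:-1] + x_edges[1:]) / 2.0
    return luts, yc, xc


def apply_clahe(img: np.ndarray, clip_limit: float = 2.0,
                tile_grid: tuple[int, int] = (8, 8)) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on a [0, 255] image.

    Tile histograms are clipped at ``clip_limit`` times the mean bin height
    (the excess redistributed uniformly), each tile gets its own equalization
    lookup table, and per-pixel outputs bilinearly interpolate between the
    four surrounding tile tables so tile seams are invisible.
    """
    if clip_limit <= 0:
        raise ConfigError("clip_limit must be positive")
    if min(tile_grid) < 1:
        raise ConfigError(f"degenerate tile grid {tile_grid}")
    img = np.asarray(img)
    if img.ndim != 2:
        raise StructuralError("apply_clahe expects a single-channel image")
    if img.min() < 0 or img.max() > 255:
        raise RangeError("apply_clahe expects values in [0, 255]")
    img8 = np.round(img).astype(np.uint8)
    luts, yc, xc = _tile_luts(img8, clip_limit, tile_grid)
    rows, cols = luts.shape[:2]
    h, w = img8.shape

    def _axis_weights(coords, centers, n):
        pos = np.clip(coords, centers[0], centers[-1])
        hi = np.searchsorted(centers, pos, side="right")
        hi = np.clip(hi, 1, n - 1) if n > 1 else np.zeros_like(hi)
        lo = hi - 1
        if n == 1:
            return np.zeros(len(coords), int), np.zeros(len(coords), int), \
                np.zeros(len(coords))
        span = centers[hi] - centers[lo]
        frac = (pos - centers[lo]) / span
        return lo, hi, frac

    ylo, yhi, fy = _axis_weights(np.arange(h, dtype=np.float64), yc, rows)
    xlo, xhi, fx = _axis_weights(np.arange(w, dtype=np.float64), xc, cols)
    Ylo, Xlo = ylo[:, None], xlo[None, :]
    Yhi, Xhi = yhi[:, None], xhi[None, :]
    Fy, Fx = fy[:, None], fx[None, :]
    v = img8
    out = ((1 - Fy) * (1 - Fx) * luts[Ylo, Xlo, v]
           + (1 - Fy) * Fx * luts[Ylo, Xhi, v]
           + Fy * (1 - Fx) * luts[Yhi, Xlo, v]
           + Fy * Fx * luts[Yhi, Xhi, v])
    return np.clip(out, 0.0, 255.0).astype(np.float32)


# ---------------------------------------------------------------------------
# bilateral filter
# ---------------------------------------------------------------------------

def apply_bilateral(img: np.ndarray, diameter: int = 9,
                    sigma_intensity: float = 30.0,
                    sigma_space: float = 75.0) -> np.ndarray:
    """Edge-preserving smoothing: Gaussian in space and in intensity.

    Every output pixel is the normalized weighted mean of its ``diameter``
    neighborhood, weights being the product of a spatial Gaussian (sigma in
    pixels) and a range Gaussian on the intensity difference (sigma in the
    image's intensity units).  Borders are reflected.
    """
    if diameter < 1 or diameter % 2 == 0:
        raise ConfigError("diameter must be an odd positive integer")
    if sigma_intensity <= 0 or sigma_space <= 0:
        raise ConfigError("sigmas must be positive")
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise StructuralError("apply_bilateral expects a single-channel image")
    r = diameter // 2
    pad = np.pad(img, r, mode="reflect")
    num = np.zeros_like(img)
    den = np.zeros_like(img)
    h, w = img.shape
    inv2ss = 1.0 / (2.0 * sigma_space ** 2)
    inv2si = 1.0 / (2.0 * sigma_intensity ** 2)
    for di in range(-r, r + 1):
        for dj in range(-r, r + 1):
            ws = np.exp(-(di * di + dj * dj) * inv2ss)
            shifted = pad[r + di:r + di + h, r + dj:r + dj + w]
            wgt = ws * np.exp(-(shifted - img) ** 2 * inv2si)
            num += wgt * shifted
            den += wgt
    return (num / den).astype(np.float32)


def enhance(img: np.ndarray, cfg: EnhanceConfig | None = None) -> np.ndarray:
    """The dual-stage enhancement: CLAHE then bilateral, order fixed.

    With ``cfg.enabled`` false the input is passed through bit-identically
    (the no-enhancement ablation).
    """
    cfg = cfg or EnhanceConfig()
    if not cfg.enabled:
        return np.asarray(img).copy()
    out = apply_clahe(img, cfg.clahe_clip_limit, cfg.clahe_tile_grid)
    return apply_bilateral(out, cfg.bilateral_diameter,
                           cfg.bilateral_sigma_intensity,
                           cfg.bilateral_sigma_space)


# ---------------------------------------------------------------------------
# resizing / normalization / reporting
# ---------------------------------------------------------------------------

def resize_pair(img: np.ndarray, mask: np.ndarray,
                size: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Resize an image (bilinear) and its mask (nearest-neighbor) jointly."""
    if size < 32:
        raise ConfigError("target size below 32 violates the network's "
                          "stride-32 constraint")
    img, mask = np.asarray(img), np.asarray(mask)
    if img.shape != mask.shape:
        raise StructuralError(f"image {img.shape} and mask {mask.shape} "
                              "must agree in shape")
    if img.shape == (size, size):
        return img.copy(), mask.copy()
    img_r = _sk_resize(img.astype(np.float64), (size, size), order=1,
                       preserve_range=True, anti_aliasing=False)
    mask_r = _sk_resize(mask, (size, size), order=0, preserve_range=True,
                        anti_aliasing=False).astype(mask.dtype)
    return img_r.astype(np.float32), mask_r


def normalize(img: np.ndarray) -> np.ndarray:
    """Map [0, 255] intensities linearly onto [0, 1]."""
    img = np.asarray(img)
    if img.min() < 0 or img.max() > 255:
        raise RangeError(f"values outside [0, 255]: min={img.min()}, "
                         f"max={img.max()}")
    return (img / 255.0).astype(np.float32)


def histogram_report(before: np.ndarray, after: np.ndarray,
                     bins: int = 256,
                     value_range: tuple[float, float] = (0.0, 256.0)
                     ) -> pd.DataFrame:
    """Per-bin pixel counts before/after enhancement (total is conserved)."""
    cb, edges = np.histogram(np.asarray(before), bins=bins, range=value_range)
    ca, _ = np.histogram(np.asarray(after), bins=bins, range=value_range)
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                         "count_before": cb, "count_after": ca})


def interdecile_range(img: np.ndarray) -> float:
    """Spread statistic used to report the contrast gain of enhancement."""
    lo, hi = np.percentile(np.asarray(img, np.float64), [10, 90])
    return float(hi - lo)


def preprocess_pair(img: np.ndarray, mask: np.ndarray, size: int = 256,
                    cfg: EnhanceConfig | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Full input standardization: enhance -> resize -> normalize."""
    out = enhance(img, cfg)
    out, mask = resize_pair(out, mask, size)
    return normalize(out), mask
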