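"""Grad-CAM explainability for the segmentation model.

For a chosen decoder feature map A with channels A_k, the class-c target is
the sum of class-c logits over the pixels predicted as class c.  The channel
weights are the spatial means of dTarget/dA_k; the raw map is
ReLU(sum_k w_k A_k), bilinearly upsampled to the input size and min-max
normalized to [0, 1] (an identically-zero map stays zero).  Overlays render
per-class heatmaps as alpha-blended color washes (LV red, myocardium green
by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, StructuralError
from .network import SegmentationNet
from .nn import tensor as T
from .nn.tensor import Tensor

DEFAULT_COLORS = {1: (1.0, 0.0, 0.0),    # LV: red
                  2: (0.0, 1.0, 0.0)}    # Myo: green


@dataclass
class CamMap:
    """A normalized class-activation map for one target class."""

    values: np.ndarray          # (H, W) floats in [0, 1]
    target_class: int
    layer_id: str

    def __post_init__(self):
        if self.values.min() < 0 or self.values.max() > 1:
            raise StructuralError("CAM values must lie in [0, 1]")


def _prepare_input(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=np.float32)
    if img.ndim == 2:
        img = np.repeat(img[None], 3, axis=0)
    if img.ndim != 3:
        raise StructuralError(f"expected (H, W) or (C, H, W) image, got "
                              f"shape {image.shape}")
    return img[None]


def grad_cam(model: SegmentationNet, image: np.ndarray, target_class: int,
             layer: str | None = None, target_pixels: str = "predicted"
             ) -> CamMap:
    """Gradient-weighted class-activation map for one class on one slice.

    ``layer`` names a decoder node (``x_0_4`` -- the final decoder feature
    map before the head -- by default).  ``target_pixels`` selects which
    logits form the scalar target: ``"predicted"`` (class-c logits where c
    is the argmax prediction; falls back to all pixels when the class is
    never predicted) or ``"all"``.
    """
    layer = layer or f"x_0_{model.decoder.depth}"
    if layer not in model.decoder.blocks:
        raise ConfigError(f"unknown decoder layer {layer!r}; available: "
                          f"{sorted(model.decoder.blocks)}")
    if target_pixels not in ("predicted", "all"):
        raise ConfigError("target_pixels must be 'predicted' or 'all'")
    if target_class == 0:
        warnings.warn("explaining the background class", stacklevel=2)
    if not 0 <= target_class < model.cfg.n_classes:
        raise ConfigError(f"target_class {target_class} out of range")
    x = _prepare_input(image)
    was_training = model.training
    model.eval()
    try:
        logits = model.forward(x)                  # graph retained
        acts = model.decoder.last_nodes[layer]
        pred = logits.data.argmax(axis=1)          # (1, H, W)
        sel = np.zeros_like(logits.data)
        if target_pixels == "predicted" and (pred == target_class).any():
            sel[0, target_class] = (pred[0] == target_class)
        else:
            sel[0, target_class] = 1.0
        target = T.tsum(T.mul(logits, sel))
        model.zero_grad()
        target.backward()
        grads = acts.grad                          # (1, C, h, w)
        weights = grads.mean(axis=(2, 3), keepdims=True)
        cam = np.maximum((weights * acts.data).sum(axis=1), 0.0)[0]
    finally:
        model.zero_grad()
        model.train(was_training)
    h, w = x.shape[2:]
    if cam.shape != (h, w):
        with T.no_grad():
            cam = T.upsample_bilinear(Tensor(cam[None, None]),
                                      size=(h, w)).data[0, 0]
        cam = np.maximum(cam, 0.0)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return CamMap(cam.astype(np.float32), target_class, layer)


def overlay(image: np.ndarray, cams: list[CamMap],
            colors: dict[int, tuple[float, float, float]] | None = None,
            alpha: float = 0.5) -> np.ndarray:
    """Alpha-composite class heatmaps over a grayscale image.

    Blending per pixel and class: out = out * (1 - alpha * cam) +
    color * alpha * cam, applied in the given cam order.  Returns an
    (H, W, 3) float array in [0, 1].
    """
    colors = colors or DEFAULT_COLORS
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise StructuralError("overlay expects a grayscale (H, W) image")
    if img.max() > 1.0:
        img = img / 255.0
    out = np.repeat(img[..., None], 3, axis=2)
    for cam in cams:
        if cam.values.shape != img.shape:
            raise StructuralError(
                f"CAM shape {cam.values.shape} does not match image "
                f"{img.shape}")
        color = np.asarray(colors.get(cam.target_class, (1.0, 1.0, 0.0)))
        a = (alpha * cam.values)[..., None]
        out = out * (1.0 - a) + color[None, None] * a
    return np.clip(out, 0.0, 1.0)


def localization_score(cam: CamMap, gt_mask: np.ndarray, target_class: int,
                       dilation_iter: int = 3) -> tuple[float, float]:
    """Mean CAM value inside vs outside the dilated ground-truth region."""
    from scipy.ndimage import binary_dilation
    region = binary_dilation(np.asarray(gt_mask) == target_class,
                             iterations=dilation_iter)
    inside = cam.values[region]
    outside = cam.values[~region]
    mean_in = float(inside.mean()) if inside.size else 0.0
    mean_out = float(outside.mean()) if outside.size else 0.0
    return mean_in, mean_out
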