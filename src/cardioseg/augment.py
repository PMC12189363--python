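"""Stochastic, anatomy-preserving data augmentation.

The policy mirrors a conservative cardiac-MRI augmentation protocol:

* horizontal flip with probability 0.5;
* mild rotation, up to 5 degrees, with probability 0.3;
* a joint shift (up to 3% of the frame) / zoom (up to 5%) / rotation (same
  5-degree limit) transform with probability 0.5;
* brightness/contrast jitter of up to 5% in either direction with
  probability 0.3 (applied to the image only, never the mask).

Geometry is applied identically to image and mask (nearest-neighbor for the
mask, so the label set can never grow); borders exposed by rotation or
shifting are filled with background (0).  When the standalone rotation and
the joint transform both fire, a single rotation angle within the shared
5-degree limit is used, so the total rotation never exceeds the limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .errors import ConfigError, StructuralError


@dataclass
class AugmentPolicy:
    p_hflip: float = 0.5
    p_rotate: float = 0.3
    rotate_limit_deg: float = 5.0
    p_ssr: float = 0.5
    shift_limit_frac: float = 0.03
    zoom_limit_frac: float = 0.05
    ssr_rotate_limit_deg: float = 5.0
    p_brightness_contrast: float = 0.3
    bc_limit_frac: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("p_hflip", "p_rotate", "p_ssr", "p_brightness_contrast"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} is not a probability")
        for name in ("rotate_limit_deg", "shift_limit_frac", "zoom_limit_frac",
                     "ssr_rotate_limit_deg", "bc_limit_frac"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


@dataclass
class TransformSpec:
    """One concrete sampled transform; applying it is deterministic."""

    flip: bool = False
    angle_deg: float = 0.0
    shift_frac: tuple[float, float] = (0.0, 0.0)
    zoom_frac: float = 0.0
    brightness_delta: float = 0.0
    contrast_delta: float = 0.0
    events: tuple[str, ...] = ()

    @property
    def is_identity(self) -> bool:
        return (not self.flip and self.angle_deg == 0.0
                and self.shift_frac == (0.0, 0.0) and self.zoom_frac == 0.0
                and self.brightness_delta == 0.0
                and self.contrast_delta == 0.0)

    def to_dict(self) -> dict:
        return {"flip": self.flip, "angle_deg": self.angle_deg,
                "shift_frac": list(self.shift_frac),
                "zoom_frac": self.zoom_frac,
                "brightness_delta": self.brightness_delta,
                "contrast_delta": self.contrast_delta,
                "events": list(self.events)}


def sample_transform(policy: AugmentPolicy,
                     rng: np.random.Generator | int | None = None
                     ) -> TransformSpec:
    """Draw one transform; each component fires independently.

    A fixed number of random variates is consumed per call, so a given
    generator state always yields the same spec.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(policy.seed if rng is None else rng)
    u = rng.random(4)
    angle_rot = rng.uniform(-policy.rotate_limit_deg, policy.rotate_limit_deg)
    dx, dy = rng.uniform(-policy.shift_limit_frac, policy.shift_limit_frac, 2)
    zoom = rng.uniform(-policy.zoom_limit_frac, policy.zoom_limit_frac)
    angle_ssr = rng.uniform(-policy.ssr_rotate_limit_deg,
                            policy.ssr_rotate_limit_deg)
    bright = rng.uniform(-policy.bc_limit_frac, policy.bc_limit_frac)
    contrast = rng.uniform(-policy.bc_limit_frac, policy.bc_limit_frac)

    flip = bool(u[0] < policy.p_hflip)
    rot_fired = bool(u[1] < policy.p_rotate)
    ssr_fired = bool(u[2] < policy.p_ssr)
    bc_fired = bool(u[3] < policy.p_brightness_contrast)

    events = tuple(name for name, fired in
                   (("hflip", flip), ("rotate", rot_fired),
                    ("shift_scale_rotate", ssr_fired),
                    ("brightness_contrast", bc_fired)) if fired)
    # both rotation events share one limit; use a single draw within it
    angle = angle_ssr if ssr_fired else (angle_rot if rot_fired else 0.0)
    return TransformSpec(
        flip=flip,
        angle_deg=float(angle),
        shift_frac=(float(dx), float(dy)) if ssr_fired else (0.0, 0.0),
        zoom_frac=float(zoom) if ssr_fired else 0.0,
        brightness_delta=float(bright) if bc_fired else 0.0,
        contrast_delta=float(contrast) if bc_fired else 0.0,
        events=events)


def _warp(arr: np.ndarray, spec: TransformSpec, order: int) -> np.ndarray:
    h, w = arr.shape
    angle = np.deg2rad(spec.angle_deg)
    scale = 1.0 + spec.zoom_frac
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, s], [-s, c]]) / scale
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    shift_px = np.array([spec.shift_frac[1] * h, spec.shift_frac[0] * w])
    # input_coord = rot @ (output_coord - center - shift) + center
    offset = center - rot @ (center + shift_px)
    return ndi.affine_transform(arr, rot, offset=offset, order=order,
                                mode="constant", cval=0.0,
                                prefilter=(order > 1))


def apply_paired(img: np.ndarray, mask: np.ndarray,
                 spec: TransformSpec) -> tuple[np.ndarray, np.ndarray]:
    """Apply one transform to an image/mask pair.

    The geometric part is shared exactly; intensity jitter touches the image
    only.  Identity specs (and pure flips) reproduce pixels bit-exactly.
    """
    img, mask = np.asarray(img), np.asarray(mask)
    if img.shape != mask.shape:
        raise StructuralError(f"image {img.shape} and mask {mask.shape} "
                              "must agree in shape")
    out_img = img.astype(np.float32, copy=True)
    out_mask = mask.copy()
    if spec.flip:
        out_img = out_img[:, ::-1].copy()
        out_mask = out_mask[:, ::-1].copy()
    if (spec.angle_deg != 0.0 or spec.zoom_frac != 0.0
            or spec.shift_frac != (0.0, 0.0)):
        out_img = _warp(out_img, spec, order=1)
        out_mask = _warp(out_mask.astype(np.float32), spec, order=0
                         ).astype(mask.dtype)
    if spec.brightness_delta != 0.0 or spec.contrast_delta != 0.0:
        vmax = 255.0 if out_img.max() > 1.5 else 1.0
        out_img = out_img * (1.0 + spec.contrast_delta) \
            + spec.brightness_delta * vmax
        out_img = np.clip(out_img, 0.0, vmax)
    return out_img.astype(np.float32), out_mask


def expand_dataset(pairs: list[tuple[np.ndarray, np.ndarray]],
                   target_count: int,
                   policy: AugmentPolicy | None = None,
                   return_specs: bool = False):
    """Grow a dataset to exactly `target_count` augmented pairs.

    Source pairs are cycled round-robin; every emitted pair gets an
    independently sampled transform.  Deterministic for a fixed
    ``policy.seed``.
    """
    policy = policy or AugmentPolicy()
    if not pairs:
        raise ConfigError("need at least one source pair")
    if target_count < len(pairs):
        raise ConfigError(f"target_count={target_count} is below the "
                          f"{len(pairs)} source pairs")
    rng = np.random.default_rng(policy.seed)
    out, specs = [], []
    for i in range(target_count):
        img, mask = pairs[i % len(pairs)]
        spec = sample_transform(policy, rng)
        out.append(apply_paired(img, mask, spec))
        specs.append(spec)
    return (out, specs) if return_specs else out
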