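"""Synthetic short-axis cardiac phantom generator.

Each slice is a bright left-ventricular blood-pool disk (class 1) enclosed by
a darker myocardial annulus (class 2) on a noisy, low-contrast background
(class 0), with a smooth multiplicative intensity bias mimicking MRI coil
shading.  Patients are stacks of 5-10 slices whose LV radius shrinks
monotonically from base toward apex.

Default intensities (background 90, myocardium 140, LV 180 on [0, 255] with
noise sigma 20) are deliberately low-contrast so that the CLAHE + bilateral
enhancement stage is consequential on phantom data.  The generator makes no
attempt at lesions, papillary muscles, or k-space artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import PatientCase
from .errors import ConfigError


@dataclass
class PhantomParams:
    """Geometry, intensity and noise parameters of the phantom.

    Radius/thickness ranges are in pixels; `for_size` scales the defaults
    (tuned for 256 x 256) to other frame sizes.
    """

    image_size: int = 256
    lv_radius_range: tuple[float, float] = (18.0, 40.0)
    myo_thickness_range: tuple[float, float] = (8.0, 15.0)
    center_jitter_frac: float = 0.05
    intensity_bg: float = 90.0
    intensity_myo: float = 140.0
    intensity_lv: float = 180.0
    bias_field_amplitude: float = 0.2
    noise_sigma: float = 20.0
    slices_per_patient_range: tuple[int, int] = (5, 10)
    apex_shrink: float = 0.55
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.slices_per_patient_range
        if not (5 <= lo <= hi <= 10):
            raise ConfigError("slices_per_patient_range must lie within [5, 10]")
        if self.lv_radius_range[0] <= 0 or self.myo_thickness_range[0] <= 0:
            raise ConfigError("radius and thickness must be positive")
        if (self.lv_radius_range[1] + self.myo_thickness_range[1]
                >= self.image_size / 2):
            raise ConfigError(
                "annulus exceeds the frame: lv_radius + myo_thickness must "
                "stay below image_size / 2")

    @classmethod
    def for_size(cls, image_size: int, **overrides) -> "PhantomParams":
        """Defaults geometrically scaled to `image_size`."""
        s = image_size / 256.0
        kw = dict(
            image_size=image_size,
            lv_radius_range=(18.0 * s, 40.0 * s),
            myo_thickness_range=(max(8.0 * s, 2.0), max(15.0 * s, 3.5)),
        )
        kw.update(overrides)
        return cls(**kw)


def _bias_field(size: int, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative shading: 1 + amplitude * quadratic polynomial."""
    if amplitude == 0:
        return np.ones((size, size), np.float32)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    u = 2.0 * xx / (size - 1) - 1.0
    v = 2.0 * yy / (size - 1) - 1.0
    coeff = rng.uniform(-1.0, 1.0, size=6)
    poly = (coeff[0] + coeff[1] * u + coeff[2] * v + coeff[3] * u * u
            + coeff[4] * u * v + coeff[5] * v * v)
    peak = np.abs(poly).max()
    if peak > 0:
        poly /= peak
    return (1.0 + amplitude * poly).astype(np.float32)


def _render_slice(params: PhantomParams, rng: np.random.Generator,
                  lv_radius: float, myo_thickness: float
                  ) -> tuple[np.ndarray, np.ndarray]:
    size = params.image_size
    if lv_radius + myo_thickness >= size / 2:
        raise ConfigError("annulus exceeds the frame for this slice geometry")
    jitter = params.center_jitter_frac * size
    cy = size / 2 + rng.uniform(-jitter, jitter)
    cx = size / 2 + rng.uniform(-jitter, jitter)
    yy, xx = np.mgrid[0:size, 0:size]
    dist = np.hypot(yy - cy, xx - cx)
    mask = np.zeros((size, size), np.uint8)
    mask[dist <= lv_radius + myo_thickness] = 2
    mask[dist <= lv_radius] = 1
    means = np.array([params.intensity_bg, params.intensity_lv,
                      params.intensity_myo], np.float32)
    img = means[mask]
    img = img * _bias_field(size, params.bias_field_amplitude, rng)
    if params.noise_sigma > 0:
        img = img + rng.normal(0.0, params.noise_sigma,
                               img.shape).astype(np.float32)
    return np.clip(img, 0.0, 255.0).astype(np.float32), mask


def generate_slice(params: PhantomParams,
                   rng: np.random.Generator | int | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """One (image, mask) pair with radius/thickness drawn from the ranges.

    Returns a float32 image on [0, 255] and a uint8 mask over {0, 1, 2}.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(params.seed if rng is None else rng)
    r = rng.uniform(*params.lv_radius_range)
    t = rng.uniform(*params.myo_thickness_range)
    return _render_slice(params, rng, r, t)


def generate_cohort(n_patients: int,
                    params: PhantomParams | None = None) -> list[PatientCase]:
    """A reproducible cohort of synthetic patients.

    Slice counts are uniform on ``slices_per_patient_range``; within a
    patient the LV radius shrinks linearly from a basal value to
    ``apex_shrink`` of it at the apex.  Patient streams are spawned
    independently from ``params.seed``, so the cohort is reproducible and
    per-patient generation order-independent.
    """
    if n_patients < 1:
        raise ConfigError("n_patients must be >= 1")
    params = params or PhantomParams()
    seeds = np.random.SeedSequence(params.seed).spawn(n_patients)
    cases = []
    for i, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        n_slices = int(rng.integers(params.slices_per_patient_range[0],
                                    params.slices_per_patient_range[1] + 1))
        r_base = rng.uniform(*params.lv_radius_range)
        thickness = rng.uniform(*params.myo_thickness_range)
        radii = np.linspace(r_base, r_base * params.apex_shrink, n_slices)
        slices, masks = [], []
        for r in radii:
            img, mask = _render_slice(params, rng, float(r), thickness)
            slices.append(img)
            masks.append(mask)
        cases.append(PatientCase(patient_id=f"P{i + 1:03d}", slices=slices,
                                 masks=masks, pathology_flag="normal"))
    return cases
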