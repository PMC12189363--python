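"""Reading, writing and splitting patient image/mask data.

The on-disk layout mirrors the public delayed-enhancement cardiac MRI
datasets this package targets: per-patient NIfTI volumes (image + mask, the
slice axis last) or per-slice PNG exports, plus a JSON manifest.  Raw masks
may carry more labels than the three segmentation classes; a `LabelMapping`
remaps them to the fixed scheme 0: background, 1: left ventricle (LV),
2: myocardium (Myo).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image

from .errors import ConfigError, LabelError, StructuralError

CLASS_NAMES = {0: "BG", 1: "LV", 2: "Myo"}
PATHOLOGY_FLAGS = ("normal", "pathological", "unknown")


@dataclass
class PatientCase:
    """Ordered slice series of one patient with per-slice label masks."""

    patient_id: str
    slices: list[np.ndarray]
    masks: list[np.ndarray]
    pathology_flag: str = "unknown"

    def __post_init__(self):
        if len(self.slices) != len(self.masks) or not self.slices:
            raise StructuralError("slices and masks must be non-empty and "
                                  "of equal length")
        shape = self.slices[0].shape
        for s, m in zip(self.slices, self.masks):
            if s.shape != shape or m.shape != shape:
                raise StructuralError("all slices and masks must share one "
                                      "H x W shape")
        if self.pathology_flag not in PATHOLOGY_FLAGS:
            raise ConfigError(f"pathology_flag must be one of "
                              f"{PATHOLOGY_FLAGS}")

    @property
    def n_slices(self) -> int:
        return len(self.slices)


@dataclass(frozen=True)
class LabelMapping:
    """Total mapping from raw mask labels to the 3-class scheme."""

    mapping: dict[int, int]
    policy: str

    def __post_init__(self):
        if not set(self.mapping.values()) <= {0, 1, 2}:
            raise ConfigError("label mapping image must be within {0, 1, 2}")

    @classmethod
    def identity(cls) -> "LabelMapping":
        return cls({0: 0, 1: 1, 2: 2}, "identity")

    @classmethod
    def merge_pathology(cls) -> "LabelMapping":
        """Fold infarct (3) and no-reflow (4) labels into myocardium.

        Pathological myocardium is still myocardium; merging keeps every
        pixel inside the 3-class scheme.
        """
        return cls({0: 0, 1: 1, 2: 2, 3: 2, 4: 2}, "merge-pathology-into-myo")

    def apply(self, raw: np.ndarray) -> np.ndarray:
        raw = np.asarray(raw)
        present = np.unique(raw)
        missing = [int(v) for v in present if int(v) not in self.mapping]
        if missing:
            raise LabelError(f"raw label value(s) {missing} not covered by "
                             f"mapping policy {self.policy!r}")
        lut = np.zeros(int(present.max()) + 1, dtype=np.uint8)
        for k, v in self.mapping.items():
            if k <= present.max():
                lut[k] = v
        return lut[raw.astype(np.int64)]


def drop_pathological(cases: list[PatientCase]) -> list[PatientCase]:
    """The alternative loading policy: keep normal cases only."""
    return [c for c in cases if c.pathology_flag == "normal"]


@dataclass
class SplitSpec:
    """Patient-level train/val/test assignment."""

    fractions: tuple[float, float, float]
    seed: int
    assignment: dict[str, str]

    def subset(self, name: str) -> list[str]:
        return [pid for pid, s in self.assignment.items() if s == name]


def split_patients(patient_ids: list[str],
                   fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
                   seed: int = 0) -> SplitSpec:
    """Reproducible patient-level split (never by slice).

    Subset sizes are round(n * fraction) with any remainder assigned to the
    training subset.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigError(f"fractions must sum to 1, got {sum(fractions)}")
    if any(f <= 0 for f in fractions):
        raise ConfigError("every fraction must be positive")
    ids = list(patient_ids)
    if len(ids) < 3:
        raise ConfigError("need at least 3 patients to fill three subsets")
    n = len(ids)
    sizes = [int(round(n * f)) for f in fractions]
    sizes[0] += n - sum(sizes)
    if min(sizes) < 0:
        raise ConfigError("fractions produce a negative subset size")
    order = np.random.default_rng(seed).permutation(n)
    assignment = {}
    cursor = 0
    for name, size in zip(("train", "val", "test"), sizes):
        for idx in order[cursor:cursor + size]:
            assignment[ids[idx]] = name
        cursor += size
    return SplitSpec(tuple(fractions), seed, assignment)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_nifti(path: Path) -> np.ndarray:
    return np.asanyarray(nib.load(str(path)).dataobj)


def _png_paths(directory: Path, prefix: str) -> list[Path]:
    return sorted(directory.glob(f"{prefix}_*.png"))


def read_case(image_path, mask_path,
              mapping: LabelMapping | None = None,
              patient_id: str | None = None,
              pathology_flag: str = "unknown") -> PatientCase:
    """Load one patient from NIfTI volumes or directories of PNG slices.

    For NIfTI, slices are taken along the last stored axis in stored order;
    intensities are kept on their raw scale.  Masks are remapped through
    `mapping` (default: the pathology-merging policy).
    """
    mapping = mapping or LabelMapping.merge_pathology()
    image_path, mask_path = Path(image_path), Path(mask_path)
    if image_path.is_dir():
        img_files = _png_paths(image_path, "image")
        msk_files = _png_paths(mask_path, "mask")
        if len(img_files) != len(msk_files) or not img_files:
            raise StructuralError(
                f"PNG directories disagree: {len(img_files)} images vs "
                f"{len(msk_files)} masks")
        slices = [np.asarray(Image.open(f)) for f in img_files]
        raw_masks = [np.asarray(Image.open(f)) for f in msk_files]
        pid = patient_id or image_path.name
    else:
        vol = _read_nifti(image_path)
        mvol = _read_nifti(mask_path)
        if vol.shape != mvol.shape:
            raise StructuralError(f"image volume {vol.shape} and mask volume "
                                  f"{mvol.shape} disagree in shape")
        if vol.ndim == 2:
            vol, mvol = vol[..., None], mvol[..., None]
        slices = [np.ascontiguousarray(vol[..., k]) for k in range(vol.shape[-1])]
        raw_masks = [np.ascontiguousarray(mvol[..., k])
                     for k in range(mvol.shape[-1])]
        pid = patient_id or image_path.name.split(".")[0]
    for s, m in zip(slices, raw_masks):
        if s.shape != m.shape:
            raise StructuralError(f"slice shape {s.shape} does not match "
                                  f"mask shape {m.shape}")
    masks = [mapping.apply(m) for m in raw_masks]
    return PatientCase(pid, slices, masks, pathology_flag)


def write_slices(case: PatientCase, out_dir, format: str = "png-slices") -> dict:
    """Write a patient case; returns (and writes) a file manifest.

    ``png-slices`` requires integer-typed arrays (8- or 16-bit grayscale);
    ``nifti-volume`` stores arrays losslessly in their own dtype.  The
    round-trip through `read_case` is exact for masks and integer images.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out_dir}: {exc}")
    manifest: dict = {"patient_id": case.patient_id, "format": format,
                      "pathology_flag": case.pathology_flag,
                      "images": [], "masks": []}
    if format == "png-slices":
        for k, (img, mask) in enumerate(zip(case.slices, case.masks)):
            if not np.issubdtype(img.dtype, np.integer):
                raise ConfigError(
                    "png-slices requires integer-typed images; round or "
                    "rescale first (or use nifti-volume)")
            ipath = out_dir / f"image_{k:03d}.png"
            mpath = out_dir / f"mask_{k:03d}.png"
            mode = "I;16" if img.dtype.itemsize > 1 else "L"
            Image.fromarray(img.astype(
                np.uint16 if mode == "I;16" else np.uint8), mode=mode
            ).save(ipath)
            Image.fromarray(mask.astype(np.uint8), mode="L").save(mpath)
            manifest["images"].append(ipath.name)
            manifest["masks"].append(mpath.name)
    elif format == "nifti-volume":
        ivol = np.stack(case.slices, axis=-1)
        mvol = np.stack(case.masks, axis=-1).astype(np.uint8)
        ipath = out_dir / f"{case.patient_id}.nii.gz"
        mpath = out_dir / f"{case.patient_id}_mask.nii.gz"
        nib.save(nib.Nifti1Image(ivol, np.eye(4)), str(ipath))
        nib.save(nib.Nifti1Image(mvol, np.eye(4)), str(mpath))
        manifest["images"].append(ipath.name)
        manifest["masks"].append(mpath.name)
    else:
        raise ConfigError(f"unknown format {format!r}; use 'png-slices' or "
                          "'nifti-volume'")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_case_from_manifest(case_dir, mapping: LabelMapping | None = None
                            ) -> PatientCase:
    """Re-read a case written by `write_slices`."""
    case_dir = Path(case_dir)
    with open(case_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    if manifest["format"] == "png-slices":
        case = read_case(case_dir, case_dir,
                         mapping or LabelMapping.identity(),
                         patient_id=manifest["patient_id"],
                         pathology_flag=manifest["pathology_flag"])
    else:
        case = read_case(case_dir / manifest["images"][0],
                         case_dir / manifest["masks"][0],
                         mapping or LabelMapping.identity(),
                         patient_id=manifest["patient_id"],
                         pathology_flag=manifest["pathology_flag"])
    return case
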