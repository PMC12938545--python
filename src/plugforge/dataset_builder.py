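"""Resampling, balanced patch extraction, and dataset export.

Training-ready cases are resampled to 0.8 mm isotropic voxels (trilinear for
images, nearest-neighbor for labels) and exported as generic image/label
NIfTI pairs with a JSON manifest. Mini-batch construction draws a fixed
ratio of plug-positive patches (centered on plug voxels) and plug-negative
patches (airway-containing regions free of plug voxels).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .errors import ConfigError, DataError
from .grid import VolumeGrid
from .intensity_transfer import AugmentConfig, apply_augmentation

__all__ = [
    "DatasetCase",
    "PatchBatch",
    "resample_isotropic",
    "extract_balanced_patches",
    "export_dataset",
]

TARGET_SPACING_MM = 0.8


@dataclass
class DatasetCase:
    """One exported training case: post-transfer CT + binary plug label."""

    case_id: str
    image: VolumeGrid
    label: VolumeGrid  # values in {0, 1}
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.image.shape != self.label.shape:
            raise DataError(f"case {self.case_id}: image/label shape mismatch")
        vals = np.unique(self.label.data)
        if not np.all(np.isin(vals, [0, 1])):
            raise DataError(f"case {self.case_id}: label values must be binary, got {vals[:10]}")


@dataclass
class PatchBatch:
    """A balanced mini-batch of (image, label) patches."""

    images: list[np.ndarray]
    labels: list[np.ndarray]
    positive: list[bool]
    ratio: tuple[int, int]
    patch_size: tuple[int, int, int]


def _to_sitk(vol: VolumeGrid) -> sitk.Image:
    img = sitk.GetImageFromArray(vol.data)
    sz, sy, sx = vol.spacing_mm
    oz, oy, ox = vol.origin_mm
    img.SetSpacing((sx, sy, sz))
    img.SetOrigin((ox, oy, oz))
    return img


def resample_isotropic(volume: VolumeGrid, target_mm: float = TARGET_SPACING_MM,
                       is_label: bool = False) -> VolumeGrid:
    """Resample to exactly ``target_mm`` isotropic spacing.

    Images use trilinear interpolation; labels nearest-neighbor, so binary
    labels stay binary. The world-coordinate extent is preserved to within
    one voxel (output size rounds ``extent / target``).
    """
    if target_mm <= 0:
        raise ConfigError("target_mm must be positive")
    arr = volume.data
    if is_label:
        arr = arr.astype(np.uint8) if arr.dtype == bool else arr
        vol = VolumeGrid(arr, volume.spacing_mm, volume.origin_mm)
    else:
        vol = VolumeGrid(arr.astype(np.float32), volume.spacing_mm, volume.origin_mm)

    img = _to_sitk(vol)
    old_size = np.asarray(img.GetSize(), dtype=float)        # (x, y, z)
    old_spacing = np.asarray(img.GetSpacing(), dtype=float)
    new_size = np.maximum(np.rint(old_size * old_spacing / target_mm), 1).astype(int)

    interp = sitk.sitkNearestNeighbor if is_label else sitk.sitkLinear
    default = 0 if is_label else float(arr.min())
    res = sitk.Resample(
        img,
        [int(n) for n in new_size],
        sitk.Transform(),
        interp,
        img.GetOrigin(),
        (target_mm, target_mm, target_mm),
        img.GetDirection(),
        default,
        img.GetPixelID(),
    )
    out = sitk.GetArrayFromImage(res)  # back to (z, y, x)
    return VolumeGrid(out, (target_mm,) * 3, volume.origin_mm)


def extract_balanced_patches(case: DatasetCase, ratio: tuple[int, int],
                             patch_size: int | tuple[int, int, int],
                             n_patches: int, rng: np.random.Generator,
                             augment: AugmentConfig | None = None,
                             max_negative_attempts: int = 2000) -> PatchBatch:
    """Sample ``n_patches`` patches at the requested positive:negative ratio.

    Positive patches are centered on uniformly drawn plug voxels (clamped so
    the patch fits); negative patches are drawn from positions whose patch
    contains airway-range attenuation but zero plug voxels. The realized
    ratio is exact when ``n_patches`` divides evenly, otherwise within one
    patch. Optional augmentation is applied per image patch.
    """
    if isinstance(patch_size, int):
        patch_size = (patch_size,) * 3
    shape = np.asarray(case.image.shape)
    ps = np.asarray(patch_size)
    if np.any(ps > shape):
        raise DataError(f"patch {tuple(patch_size)} does not fit in volume {tuple(shape)}")
    p, q = ratio
    if p < 0 or q < 0 or p + q == 0:
        raise ConfigError(f"invalid ratio {ratio}")
    n_pos = int(round(n_patches * p / (p + q)))
    n_neg = n_patches - n_pos

    plug_vox = np.argwhere(case.label.data > 0)
    if n_pos > 0 and len(plug_vox) == 0:
        raise DataError("positive patches requested but the case has no plug voxels")

    def corner_for(center: np.ndarray) -> np.ndarray:
        c = center - ps // 2
        return np.clip(c, 0, shape - ps)

    images, labels, flags = [], [], []
    for _ in range(n_pos):
        center = plug_vox[rng.integers(len(plug_vox))]
        c = corner_for(center)
        sl = tuple(slice(c[i], c[i] + ps[i]) for i in range(3))
        images.append(case.image.data[sl])
        labels.append(case.label.data[sl])
        flags.append(True)

    label_data = case.label.data
    image_data = case.image.data
    placed = 0
    for _ in range(max_negative_attempts):
        if placed >= n_neg:
            break
        c = np.array([rng.integers(0, shape[i] - ps[i] + 1) for i in range(3)])
        sl = tuple(slice(c[i], c[i] + ps[i]) for i in range(3))
        if label_data[sl].sum() > 0:
            continue
        # require airway-like content: some near-air attenuation in the patch
        if image_data[sl].min() > -500:
            continue
        images.append(image_data[sl])
        labels.append(label_data[sl])
        flags.append(False)
        placed += 1
    if placed < n_neg:
        raise DataError(f"could only place {placed} of {n_neg} negative patches")

    if augment is not None:
        spacing = case.image.spacing_mm
        images = [
            apply_augmentation(im, augment, rng, spacing_mm=spacing) for im in images
        ]
    return PatchBatch(images, labels, flags, (p, q), tuple(int(v) for v in ps))


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def export_dataset(cases: list[DatasetCase], out_dir: str | Path,
                   force: bool = False, naming: str = "{case_id}_{kind}.nii.gz") -> dict:
    """Write image/label NIfTI pairs plus a JSON manifest; returns the manifest.

    Refuses to write into an existing non-empty directory unless ``force``.
    Round-trip reading the written files reproduces the arrays bit-exactly.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise DataError(f"output directory {out} is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)

    entries = []
    total_plug_voxels = 0
    for case in cases:
        img_path = out / naming.format(case_id=case.case_id, kind="image")
        lab_path = out / naming.format(case_id=case.case_id, kind="label")
        case.image.save(img_path)
        label = case.label
        if label.data.dtype == bool:
            label = label.with_data(label.data.astype(np.uint8))
        label.save(lab_path)
        plug_voxels = int(np.count_nonzero(case.label.data))
        total_plug_voxels += plug_voxels
        entries.append(
            {
                "case_id": case.case_id,
                "image": img_path.name,
                "label": lab_path.name,
                "spacing_mm": list(case.image.spacing_mm),
                "shape": list(case.image.shape),
                "plug_voxels": plug_voxels,
                "n_plugs": case.provenance.get("n_plugs"),
                "provenance": case.provenance,
            }
        )
    manifest = {
        "n_cases": len(cases),
        "total_plugs": sum(e["n_plugs"] or 0 for e in entries),
        "total_plug_voxels": total_plug_voxels,
        "cases": entries,
    }
    manifest["config_hash"] = _config_hash(manifest)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
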