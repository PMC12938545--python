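"""3-D volume container and NIfTI I/O.

Conventions: arrays are indexed (z, y, x), voxel indices are 0-based, world
coordinates are in millimetres with ``world = origin + index * spacing`` per
axis (identity orientation). On disk, volumes follow the NIfTI convention of
(x, y, z) ordering with a diagonal affine; the transpose happens at the I/O
boundary only.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import DataError

__all__ = ["VolumeGrid"]


@dataclass
class VolumeGrid:
    """A 3-D scalar or integer lattice with physical spacing and origin.

    Parameters
    ----------
    data:
        Array of shape (nz, ny, nx). HU values, binary masks, or labels.
    spacing_mm:
        Per-axis voxel size (sz, sy, sx), strictly positive.
    origin_mm:
        World coordinate of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DataError(f"VolumeGrid data must be 3-D, got ndim={self.data.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise DataError(f"spacing_mm must be 3 positive values, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) in (z,y,x) order to world mm."""
        idx = np.asarray(idx, dtype=float)
        return idx * np.asarray(self.spacing_mm) + np.asarray(self.origin_mm)

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Map world mm (..., 3) to fractional voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm)

    def with_data(self, data: np.ndarray) -> "VolumeGrid":
        """New grid sharing this grid's geometry."""
        return VolumeGrid(data, self.spacing_mm, self.origin_mm)

    # ------------------------------------------------------------------ I/O

    def _affine(self) -> np.ndarray:
        sz, sy, sx = self.spacing_mm
        oz, oy, ox = self.origin_mm
        aff = np.diag([sx, sy, sz, 1.0])
        aff[:3, 3] = [ox, oy, oz]
        return aff

    def save(self, path: str | Path) -> None:
        """Write as NIfTI (.nii or .nii.gz).

        Gzip members are written with mtime=0 so identical volumes produce
        byte-identical files.
        """
        path = Path(path)
        arr = self.data
        if arr.dtype == bool:
            arr = arr.astype(np.uint8)
        img = nib.Nifti1Image(np.transpose(arr, (2, 1, 0)), self._affine())
        img.header.set_data_dtype(arr.dtype)
        if path.name.endswith(".gz"):
            payload = img.to_bytes()
            with open(path, "wb") as f:
                with gzip.GzipFile(fileobj=f, mode="wb", mtime=0) as gz:
                    gz.write(payload)
        else:
            nib.save(img, str(path))

    @classmethod
    def load(cls, path: str | Path) -> "VolumeGrid":
        img = nib.load(str(path))
        arr = np.transpose(np.asanyarray(img.dataobj), (2, 1, 0))
        aff = img.affine
        spacing = (float(aff[2, 2]), float(aff[1, 1]), float(aff[0, 0]))
        origin = (float(aff[2, 3]), float(aff[1, 3]), float(aff[0, 3]))
        return cls(arr, spacing, origin)
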