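"""Minimal 3-D volume container used across the package.

All volumes in a study share one voxel grid with axis order (x, y, z),
0-based indices, and a voxel size in millimetres.  NIfTI-1 is the on-disk
format; the affine is a plain diagonal scaling (phantom data are generated
pre-aligned, so no registration metadata is carried).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VolumeMap"]


@dataclass
class VolumeMap:
    """A 3-D scalar, label or mask field on a common voxel grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values.  Masks are boolean or {0, 1}; missing values are NaN.
    voxel_size_mm : tuple of float
        Voxel edge lengths along (x, y, z), in mm.
    meta : dict
        Free-form metadata (e.g. ``acquisition_midpoint_min``).
    """

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"VolumeMap requires a 3-D array, got ndim={self.values.ndim}")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be three positive lengths")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_ul(self) -> float:
        """Volume of one voxel in microlitres (mm^3)."""
        vx, vy, vz = self.voxel_size_mm
        return vx * vy * vz

    def same_grid(self, other: "VolumeMap") -> bool:
        return self.shape == other.shape and np.allclose(
            self.voxel_size_mm, other.voxel_size_mm
        )

    def require_same_grid(self, other: "VolumeMap", what: str = "volume") -> None:
        if not self.same_grid(other):
            raise ValueError(
                f"grid mismatch: {what} has shape {other.shape} / voxel "
                f"{other.voxel_size_mm}, expected {self.shape} / {self.voxel_size_mm}"
            )

    # -- NIfTI round trip ---------------------------------------------------

    def to_nifti(self, path) -> None:
        affine = np.diag(list(self.voxel_size_mm) + [1.0])
        img = nib.Nifti1Image(np.asarray(self.values, dtype=np.float32), affine)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path, meta: dict | None = None) -> "VolumeMap":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        return cls(np.asanyarray(img.dataobj), tuple(float(z) for z in zooms),
                   dict(meta or {}))
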