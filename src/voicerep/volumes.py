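"""Volumetric maps (probability atlases, t-statistic maps, beta images).

Thin container around a 3D array plus a voxel-to-millimetre affine, with
NIfTI round-tripping through nibabel. All spatial reasoning elsewhere in
the package (nearest-voxel ROI growth, local-maximum search) happens in
millimetre space through the affine, so anisotropic voxels are handled
correctly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import InvalidArgumentError

VOLUME_KINDS = ("probability", "tstat", "beta")


@dataclass
class VolumeMap:
    grid: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    kind: str = "beta"

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.grid.ndim != 3 or min(self.grid.shape) < 1:
            raise InvalidArgumentError("grid must be a non-empty 3D array")
        if self.affine.shape != (4, 4):
            raise InvalidArgumentError("affine must be 4x4")
        if self.kind not in VOLUME_KINDS:
            raise InvalidArgumentError(f"unknown volume kind {self.kind!r}")
        if self.kind == "probability":
            finite = self.grid[np.isfinite(self.grid)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise InvalidArgumentError("probability maps must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def voxel_to_mm(self, voxels: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel indices to (n, 3) millimetre coordinates."""
        voxels = np.atleast_2d(np.asarray(voxels, dtype=float))
        hom = np.c_[voxels, np.ones(len(voxels))]
        return (self.affine @ hom.T).T[:, :3]

    def same_space(self, other: "VolumeMap") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)

    # ------------------------------------------------------------------ I/O
    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.grid.astype(np.float32), self.affine)

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path: str | Path, kind: str = "beta") -> "VolumeMap":
        img = nib.load(str(path))
        return cls(grid=np.asarray(img.get_fdata(), dtype=float),
                   affine=np.asarray(img.affine), kind=kind)
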