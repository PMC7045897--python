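"""3D image volume container and NIfTI I/O.

Arrays are stored in ``(slices, rows, cols)`` axis order, i.e. ``(z, y, x)``;
``spacing`` and ``origin`` use the same order, in millimetres.  NIfTI files
are written with an RAS-diagonal affine encoding spacing and origin, and the
array transposed to the on-disk ``(x, y, z)`` convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Volume", "read_nifti", "write_nifti"]


@dataclass
class Volume:
    """A 3D scalar image with voxel spacing and physical origin.

    Parameters
    ----------
    values : ndarray, shape (slices, rows, cols)
        Voxel data.
    spacing : tuple of float
        Voxel size in mm per axis, ``(slice, row, col)`` order.
    origin : tuple of float
        Physical position (mm) of the center of voxel ``(0, 0, 0)``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError(f"volume grid must be 3D and non-empty, got shape {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three strictly positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def with_values(self, values: np.ndarray, spacing=None, origin=None) -> "Volume":
        """Copy of this volume carrying new voxel data (and optionally new geometry)."""
        return Volume(
            values=values,
            spacing=self.spacing if spacing is None else spacing,
            origin=self.origin if origin is None else origin,
        )

    def is_binary(self) -> bool:
        return bool(np.isin(self.values, (0, 1)).all())

    def voxel_centers_physical(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates (mm) of voxel centers along each axis."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a], dtype=float)
            for a in range(3)
        )  # type: ignore[return-value]

    def copy(self) -> "Volume":
        return replace(self, values=self.values.copy())


def _affine(vol: Volume) -> np.ndarray:
    aff = np.eye(4)
    # on-disk order is (x, y, z) = reversed array order
    for i, a in enumerate((2, 1, 0)):
        aff[i, i] = vol.spacing[a]
        aff[i, 3] = vol.origin[a]
    return aff


def write_nifti(vol: Volume, path: str | Path) -> Path:
    """Write a volume as (optionally gzipped) NIfTI, encoding spacing in the affine."""
    path = Path(path)
    img = nib.Nifti1Image(np.transpose(vol.values, (2, 1, 0)), _affine(vol))
    nib.save(img, str(path))
    return path


def read_nifti(path: str | Path) -> Volume:
    """Read a NIfTI file produced by :func:`write_nifti` (diagonal affine)."""
    img = nib.load(str(path))
    aff = img.affine
    data = np.asarray(img.dataobj)
    values = np.transpose(data, (2, 1, 0))
    spacing = tuple(float(abs(aff[i, i])) for i in (2, 1, 0))
    origin = tuple(float(aff[i, 3]) for i in (2, 1, 0))
    return Volume(values=values, spacing=spacing, origin=origin)
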