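"""Volume container and NIfTI readers/writers.

The in-memory axis order is (x, y, z) ascending and the NIfTI affine is
carried through untouched, so no silent reorientation happens on load.
Displacement fields are stored as 4-D NIfTI with the last axis holding the
three components; the unit convention (normalized vs voxel) is recorded in
the header description string.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["Volume", "read_nifti", "read_labels", "write_nifti", "write_field", "resample_to"]


class ImageIOError(IOError):
    """Typed error for malformed or unexpected image files."""


@dataclass
class Volume:
    """A 3-D scalar grid with voxel spacing and world affine."""

    values: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3-D, got {self.values.ndim} axes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def shape(self):
        return self.values.shape

    def normalized(self) -> "Volume":
        """Min-max rescale intensities to [0, 1]."""
        v = self.values.astype(np.float64)
        lo, hi = v.min(), v.max()
        if hi > lo:
            v = (v - lo) / (hi - lo)
        else:
            v = np.zeros_like(v)
        return Volume(v, self.spacing, self.affine)


def _load(path):
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise
    except Exception as e:  # malformed header etc.
        raise ImageIOError(f"cannot read NIfTI file {path}: {e}") from e
    return img


def read_nifti(path) -> Volume:
    """Read a 3-D scalar NIfTI volume."""
    img = _load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ImageIOError(f"{path}: expected a 3-D volume, got {data.ndim} axes")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(np.asarray(data), spacing=spacing, affine=np.asarray(img.affine))


def read_labels(path) -> np.ndarray:
    """Read an integer label volume."""
    img = _load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ImageIOError(f"{path}: expected a 3-D label volume, got {data.ndim} axes")
    return np.asarray(np.rint(data), dtype=np.int32)


def read_field(path) -> np.ndarray:
    """Read a displacement field stored as 4-D NIfTI (last axis = 3)."""
    img = _load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ImageIOError(f"{path}: expected a 4-D field with 3 components")
    return np.asarray(data, dtype=np.float64)


def write_nifti(volume, path, affine=None) -> None:
    """Write a Volume or a raw array (labels kept integer) to NIfTI."""
    if isinstance(volume, Volume):
        data, affine = volume.values, volume.affine
    else:
        data = np.asarray(volume)
        affine = np.eye(4) if affine is None else affine
    if np.issubdtype(data.dtype, np.integer):
        img = nib.Nifti1Image(data.astype(np.int32), affine)
    else:
        img = nib.Nifti1Image(data.astype(np.float32), affine)
    nib.save(img, str(path))


def write_field(field: np.ndarray, path, affine=None, units: str = "normalized") -> None:
    """Write a dense displacement field; the unit is recorded in the header."""
    field = np.asarray(field, dtype=np.float32)
    if field.ndim != 4 or field.shape[-1] != 3:
        raise ValueError("field must be (X, Y, Z, 3)")
    img = nib.Nifti1Image(field, np.eye(4) if affine is None else affine)
    img.header["descrip"] = f"displacement {units} units, last axis = xyz".encode()
    nib.save(img, str(path))


def resample_to(volume: Volume, reference: Volume, mode: str = "linear") -> Volume:
    """Resample a volume onto the grid of ``reference`` through the affines."""
    from scipy.ndimage import map_coordinates

    order = {"linear": 1, "nearest": 0}[mode]
    ref_idx = np.indices(reference.shape).reshape(3, -1)
    homog = np.vstack([ref_idx, np.ones((1, ref_idx.shape[1]))])
    world = reference.affine @ homog
    src_idx = (np.linalg.inv(volume.affine) @ world)[:3]
    values = map_coordinates(
        volume.values.astype(np.float64), src_idx, order=order, mode="nearest"
    ).reshape(reference.shape)
    if np.issubdtype(volume.values.dtype, np.integer):
        values = np.rint(values).astype(volume.values.dtype)
    return Volume(values, reference.spacing, reference.affine)
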