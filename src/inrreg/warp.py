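"""Apply deformation fields to volumes and label maps.

The convention throughout the package is *pull-back* resampling: the moved
image at grid coordinate x takes the value of the input volume sampled at
Phi(x) = x + displacement(x).  Out-of-range sample positions are clamped to
the border.  Images use trilinear interpolation, label maps nearest
neighbor (so no new label values can appear).
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates

from .coords import normalize_grid

__all__ = ["apply_field", "warp_labels", "dense_displacement"]


def dense_displacement(field, shape) -> np.ndarray:
    """Evaluate a field's displacement on the full grid -> (X, Y, Z, 3)."""
    if isinstance(field, np.ndarray):
        if field.shape != (*shape, 3):
            raise ValueError(f"dense field shape {field.shape} != {(*shape, 3)}")
        return field
    grid = normalize_grid(shape)
    disp = field.displacement(grid.points)
    return np.asarray(disp).reshape(*shape, 3)


def _sample_indices(field, shape) -> np.ndarray:
    disp = dense_displacement(field, shape)
    if not np.all(np.isfinite(disp)):
        bad = np.argwhere(~np.isfinite(disp).all(axis=-1))[0]
        raise FloatingPointError(
            "non-finite field value at voxel "
            f"({int(bad[0])}, {int(bad[1])}, {int(bad[2])})"
        )
    # sample index = voxel index + displacement in voxel units; computed this
    # way a zero displacement lands exactly on the interpolation nodes
    scale = (np.asarray(shape, dtype=np.float64) - 1.0) / 2.0
    idx = np.indices(shape, dtype=np.float64).reshape(3, -1)
    idx += (disp.reshape(-1, 3) * scale).T
    return idx  # (3, N) for map_coordinates


def apply_field(volume, field, mode: str = "linear"):
    """Resample ``volume`` through the deformation x -> x + field(x).

    ``volume`` may be a Volume or a plain 3-D array; ``field`` is either an
    object with ``displacement(points)`` or a dense (X, Y, Z, 3) array of
    normalized-unit displacements.  Returns the same container type.
    """
    from .image_io import Volume

    values = volume.values if isinstance(volume, Volume) else np.asarray(volume)
    order = {"linear": 1, "nearest": 0}[mode]
    idx = _sample_indices(field, values.shape)
    moved = map_coordinates(
        values.astype(np.float64), idx, order=order, mode="nearest"
    ).reshape(values.shape)
    if isinstance(volume, Volume):
        return Volume(moved, volume.spacing, volume.affine)
    return moved


def warp_labels(labels: np.ndarray, field) -> np.ndarray:
    """Nearest-neighbor pull-back of an integer label map."""
    labels = np.asarray(labels)
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValueError("labels must be an integer array")
    idx = _sample_indices(field, labels.shape)
    warped = map_coordinates(labels, idx, order=0, mode="nearest")
    return warped.reshape(labels.shape).astype(labels.dtype)
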