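"""Normalized coordinate grids, Fourier positional encoding, patch sampling.

Coordinates are voxel-centered and normalized to [-1, 1]^3: voxel index
``i`` along an axis of length ``d`` maps to ``2*i/(d-1) - 1`` (axes of
length 1 map to 0).  Voxels are enumerated in C order (last axis fastest),
so ``CoordGrid.points[k]`` corresponds to ``np.unravel_index(k, shape)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concat

__all__ = [
    "CoordGrid",
    "PatchSpec",
    "normalize_grid",
    "index_to_coord",
    "coord_to_index",
    "fourier_encode",
    "fourier_encode_t",
    "encoding_length",
    "sample_patches",
]


@dataclass(frozen=True)
class CoordGrid:
    """Dense normalized coordinate grid for a 3-D volume."""

    shape: tuple
    points: np.ndarray  # (prod(shape), 3) in [-1, 1]

    def reshape_points(self) -> np.ndarray:
        return self.points.reshape(*self.shape, 3)


@dataclass(frozen=True)
class PatchSpec:
    """Random cubic patch sampling configuration."""

    patch_size: int = 32
    patches_per_epoch: int = 500
    seed: int = 0


def _axis_coords(dim: int) -> np.ndarray:
    if dim < 1:
        raise ValueError(f"axis dimension must be >= 1, got {dim}")
    if dim == 1:
        return np.zeros(1)
    return 2.0 * np.arange(dim) / (dim - 1) - 1.0


def normalize_grid(shape) -> CoordGrid:
    """Build the dense voxel-centered coordinate grid of a volume."""
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3:
        raise ValueError("shape must have three dimensions")
    axes = [_axis_coords(d) for d in shape]
    mesh = np.meshgrid(*axes, indexing="ij")
    points = np.stack([m.ravel() for m in mesh], axis=-1)
    return CoordGrid(shape=shape, points=points)


def index_to_coord(index, shape) -> np.ndarray:
    """Map voxel indices (N, 3) to normalized coordinates."""
    index = np.asarray(index, dtype=np.float64)
    dims = np.asarray(shape, dtype=np.float64)
    denom = np.where(dims > 1, dims - 1.0, 1.0)
    out = 2.0 * index / denom - 1.0
    return np.where(dims > 1, out, 0.0)

def coord_to_index(coord, shape) -> np.ndarray:
    """Map normalized coordinates to (fractional) voxel indices."""
    coord = np.asarray(coord, dtype=np.float64)
    dims = np.asarray(shape, dtype=np.float64)
    return (coord + 1.0) * 0.5 * (dims - 1.0)


def encoding_length(n_freq: int) -> int:
    return 3 * (1 + 2 * n_freq)


def fourier_encode(x: np.ndarray, n_freq: int = 6, base: float = np.pi) -> np.ndarray:
    """Positional encoding ``[x, sin(2^k b x), cos(2^k b x)]_{k<n_freq}``.

    Applied component-wise; for the default six frequencies a 3-vector maps
    to a 39-vector.  ``base`` selects between 2^k*pi (default) and 2^k
    frequency conventions.
    """
    if n_freq < 1:
        raise ValueError("n_freq must be >= 1")
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    parts = [x]
    for k in range(n_freq):
        arg = (2.0**k) * base * x
        parts.append(np.sin(arg))
        parts.append(np.cos(arg))
    return np.concatenate(parts, axis=-1)


def fourier_encode_t(x: Tensor, n_freq: int = 6, base: float = np.pi,
                     with_jac: bool = True, J0=None):
    """Encoding as engine ops, optionally with its input-Jacobian.

    Returns ``(enc, J)`` where ``enc`` has shape (N, 3*(1+2*n_freq)) and
    ``J`` has shape (N, 3, features): ``J[n, i, f] = d enc_f / d x_i``
    (None when ``with_jac`` is false).  The encoding acts per component, so
    each feature block is diagonal in the component index.  ``J0``
    (N, 3, 3) optionally seeds the chain rule with the Jacobian of ``x``
    w.r.t. an upstream coordinate.
    """
    if n_freq < 1:
        raise ValueError("n_freq must be >= 1")
    n = x.shape[0]
    if with_jac and J0 is None:
        eye = np.eye(3, dtype=x.data.dtype)
        J0 = Tensor(np.broadcast_to(eye, (n, 3, 3)).copy())
    parts = [x]
    jparts = [J0] if with_jac else None
    for k in range(n_freq):
        w = (2.0**k) * base
        arg = x * w
        s, c = arg.sin(), arg.cos()
        parts.append(s)
        parts.append(c)
        if with_jac:
            # d sin(w x_j)/d x_i = w cos(w x_j) * d x_j/d x_i
            jparts.append(J0 * (c * w).reshape(n, 1, 3))
            jparts.append(J0 * (s * (-w)).reshape(n, 1, 3))
    enc = concat(parts, axis=-1)
    return enc, (concat(jparts, axis=-1) if with_jac else None)


def sample_patches(shape, spec: PatchSpec) -> np.ndarray:
    """Draw uniform random corner indices of cubic patches, with replacement.

    Returns an integer array (patches_per_epoch, 3); the patch at corner c
    covers voxels ``c : c + patch_size`` on every axis.  Deterministic for a
    fixed seed.
    """
    shape = tuple(int(s) for s in shape)
    w = spec.patch_size
    if any(w > s for s in shape):
        raise ValueError(f"patch size {w} exceeds volume shape {shape}")
    rng = np.random.default_rng(spec.seed)
    hi = np.asarray([s - w + 1 for s in shape])
    return rng.integers(0, hi, size=(spec.patches_per_epoch, 3))


def patch_coords(corner, patch_size: int, shape) -> np.ndarray:
    """Normalized coordinates of every voxel of one cubic patch (C order)."""
    idx = [np.arange(c, c + patch_size) for c in corner]
    mesh = np.meshgrid(*idx, indexing="ij")
    index = np.stack([m.ravel() for m in mesh], axis=-1)
    return index_to_coord(index, shape)
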