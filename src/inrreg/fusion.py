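"""Registration-guided image fusion.

A second coordinate network outputs per-voxel weights on the 3-simplex
(via normalized exponentials) that mix the raw moving image with its
Laplacian-filtered (edge-enhancing) and Gaussian-filtered (smoothing)
versions; the fused image is trained jointly with the deformation network
so that regions pick whichever filtering helps the alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, laplace

from ._autodiff import Tensor
from .image_io import Volume

__all__ = ["FilteredChannels", "make_channels", "simplex_weights", "fuse", "weight_map_rgb"]


@dataclass
class FilteredChannels:
    """The moving image and its Laplacian / Gaussian filtered versions."""

    m: np.ndarray
    m_l: np.ndarray
    m_g: np.ndarray

    def __post_init__(self):
        if not (self.m.shape == self.m_l.shape == self.m_g.shape):
            raise ValueError("channels must share shape")

    def stack(self) -> np.ndarray:
        return np.stack([self.m, self.m_l, self.m_g], axis=-1)


def make_channels(moving, gaussian_sigma: float = 1.0) -> FilteredChannels:
    """Build the three fusion channels.

    The Gaussian channel uses reflective boundaries; the Laplacian channel
    is the 6-connected discrete Laplacian min-max rescaled to [0, 1] so all
    channels share the intensity range and the simplex weights stay
    interpretable.  A constant image has zero Laplacian response and maps
    to an all-zero channel.
    """
    m = moving.values if isinstance(moving, Volume) else np.asarray(moving)
    m = m.astype(np.float64)
    m_g = gaussian_filter(m, gaussian_sigma, mode="reflect") if gaussian_sigma > 0 else m.copy()
    m_l = laplace(m, mode="reflect")
    lo, hi = m_l.min(), m_l.max()
    m_l = (m_l - lo) / (hi - lo) if hi > lo else np.zeros_like(m_l)
    return FilteredChannels(m=m, m_l=m_l, m_g=m_g)


def simplex_weights(logits) -> Tensor:
    """Map 3 logits per coordinate to the probability simplex (sums to 1)."""
    z = Tensor.as_tensor(logits)
    shift = z.data.max(axis=-1, keepdims=True)  # constant: stabilizes exp
    e = (z - shift).exp()
    return e / e.sum(axis=-1, keepdims=True)


def fuse(channels: FilteredChannels, weights) -> np.ndarray:
    """Voxel-wise convex combination M' = s_M M + s_L M_L + s_G M_G."""
    w = weights.data if isinstance(weights, Tensor) else np.asarray(weights)
    stacked = channels.stack()
    if w.shape != stacked.shape[-w.ndim:] and w.reshape(-1, 3).shape[0] != stacked[..., 0].size:
        raise ValueError("weights incompatible with channel shape")
    w = w.reshape(*stacked.shape[:-1], 3)
    return (stacked * w).sum(axis=-1)


def fuse_t(channel_values: np.ndarray, weights: Tensor) -> Tensor:
    """Engine fusion of sampled channel values (N, 3) with weights (N, 3)."""
    return (weights * channel_values).sum(axis=-1)


def save_weight_preview(weights: np.ndarray, path, axis: int = 2) -> None:
    """Write the mid-slice of a 3-D weight grid as an RGB PNG preview."""
    from PIL import Image

    w = np.asarray(weights)
    if w.ndim != 4 or w.shape[-1] != 3:
        raise ValueError("expected a (X, Y, Z, 3) weight grid")
    mid = w.shape[axis] // 2
    slicer = [slice(None)] * 3
    slicer[axis] = mid
    rgb, _ = weight_map_rgb(w[tuple(slicer)])
    Image.fromarray(rgb, mode="RGB").save(str(path))


def weight_map_rgb(weights: np.ndarray):
    """Render a weight grid as 8-bit RGB plus per-component mean weights.

    Red = raw image weight, green = Laplacian, blue = Gaussian; means are
    rounded to two decimals for logging.
    """
    w = np.asarray(weights, dtype=np.float64)
    rgb = np.rint(255.0 * w).astype(np.uint8)
    means = w.reshape(-1, 3).mean(axis=0)
    return rgb, tuple(round(float(x), 2) for x in means)
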