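"""Training objectives: similarity, Jacobian regularization, cycle, fusion.

All losses are written in autodiff-engine operations so they can drive the
optimization; plain numpy arrays are accepted and wrapped, and scalar
results can be read with ``.item()``.

Similarity is |1 - NCC| over the whole patch plus the mean of |1 - NCC|
over 9x9x9 sliding windows (local NCC), both with a small epsilon inside
the denominator square root to guard constant windows.  The deformation
regularizer penalizes the mean |1 - |J_Phi|| over sampled coordinates,
where |J_Phi| is the signed Jacobian determinant obtained by automatic
differentiation; folding (non-positive determinants) is reported separately
by :mod:`inrreg.metrics`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, box_sum3

__all__ = [
    "LossWeights",
    "LossReport",
    "ncc_loss",
    "lncc_loss",
    "similarity_loss",
    "jacobian_reg",
    "jacobian_det",
    "cycle_loss",
    "fusion_loss",
    "total_loss",
]

NCC_EPS = 1e-5


@dataclass
class LossWeights:
    """Weights balancing the loss terms (alpha_reg default 0.1, alpha_cyc 100)."""

    alpha_reg: float = 0.1
    alpha_cyc: float = 100.0

    def __post_init__(self):
        if not (np.isfinite(self.alpha_reg) and np.isfinite(self.alpha_cyc)):
            raise ValueError("loss weights must be finite")
        if self.alpha_reg < 0 or self.alpha_cyc < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class LossReport:
    """Per-step scalar loss terms; ``total`` is their documented weighted sum."""

    similarity: float = 0.0
    ncc: float = 0.0
    lncc: float = 0.0
    regularization: float = 0.0
    cycle: float = 0.0
    fusion: float = 0.0
    total: float = 0.0

    @staticmethod
    def csv_header() -> str:
        return "epoch,similarity,ncc,lncc,regularization,cycle,fusion,total"

    def csv_row(self, epoch: int) -> str:
        return (f"{epoch},{self.similarity:.8g},{self.ncc:.8g},{self.lncc:.8g},"
                f"{self.regularization:.8g},{self.cycle:.8g},{self.fusion:.8g},"
                f"{self.total:.8g}")


def _pair(f, m):
    f, m = Tensor.as_tensor(f), Tensor.as_tensor(m)
    if f.shape != m.shape:
        raise ValueError(f"patch shapes differ: {f.shape} vs {m.shape}")
    return f, m


def ncc_loss(f_patch, m_patch) -> Tensor:
    """|1 - NCC| over the whole patch."""
    f, m = _pair(f_patch, m_patch)
    if f.data.size < 2:
        raise ValueError("patches must contain at least 2 voxels")
    fc = f - f.mean()
    mc = m - m.mean()
    num = (fc * mc).sum()
    den = ((fc * fc).sum() * (mc * mc).sum() + NCC_EPS).sqrt()
    return (1.0 - num / den).abs()


def lncc_loss(f_patch, m_patch, window: int = 9) -> Tensor:
    """Mean of |1 - NCC| over valid sliding windows (stride 1)."""
    f, m = _pair(f_patch, m_patch)
    if f.ndim != 3:
        raise ValueError("lncc_loss expects 3-D patches")
    if window > min(f.shape):
        raise ValueError(f"window {window} exceeds patch shape {f.shape}")
    n = float(window**3)
    sf = box_sum3(f, window)
    sm = box_sum3(m, window)
    sff = box_sum3(f * f, window)
    smm = box_sum3(m * m, window)
    sfm = box_sum3(f * m, window)
    cov = sfm - sf * sm * (1.0 / n)
    varf = sff - sf * sf * (1.0 / n)
    varm = smm - sm * sm * (1.0 / n)
    ncc = cov / (varf * varm + NCC_EPS).sqrt()
    return (1.0 - ncc).abs().mean()


def similarity_loss(f_patch, m_patch, window: int = 9):
    """NCC plus local-NCC similarity; returns (total, ncc, lncc)."""
    n = ncc_loss(f_patch, m_patch)
    l = lncc_loss(f_patch, m_patch, window)
    return n + l, n, l


def jacobian_det(J_disp: Tensor) -> Tensor:
    """Signed determinant of Phi's Jacobian from the displacement Jacobian.

    ``J_disp[n, i, j] = d dx_j / d x_i``; the determinant of I + J_disp is
    unchanged by the transpose, so no reordering is needed.
    """
    J = J_disp + np.eye(3, dtype=J_disp.data.dtype)
    a00, a01, a02 = J[:, 0, 0], J[:, 0, 1], J[:, 0, 2]
    a10, a11, a12 = J[:, 1, 0], J[:, 1, 1], J[:, 1, 2]
    a20, a21, a22 = J[:, 2, 0], J[:, 2, 1], J[:, 2, 2]
    return (
        a00 * (a11 * a22 - a12 * a21)
        - a01 * (a10 * a22 - a12 * a20)
        + a02 * (a10 * a21 - a11 * a20)
    )


def jacobian_reg(model, coords) -> Tensor:
    """Mean |1 - |J_Phi|| over the coordinate batch, by autodiff.

    ``model`` is anything with ``displace_t(coords, with_jac=True)`` — a
    coordinate network, variant wrapper, or analytic field (whose engine
    form is differentiated by the same tape).
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=np.float64))
    if hasattr(model, "displace_t") and not _is_analytic(model):
        _, J = model.displace_t(coords, with_jac=True)
        det = jacobian_det(J)
    else:
        det = _autodiff_det_of_callable(model, coords)
    return (1.0 - det).abs().mean()


def _is_analytic(model) -> bool:
    return hasattr(model, "kind") and not hasattr(model, "config")


def _autodiff_det_of_callable(field, coords) -> Tensor:
    """Determinant of an analytic field's Phi via the engine tape.

    Builds the displacement with engine ops from a coordinate Tensor and
    extracts each Jacobian column by a reverse sweep; used for oracle
    cross-checks against the closed-form Jacobians.
    """
    cols = []
    for j in range(3):
        x = Tensor(coords, requires_grad=True)
        dx = field.displace_t(x)
        comp = dx[:, j].sum()
        comp.backward()
        cols.append(x.grad.copy())
    # cols[j][n, i] = d dx_j / d x_i
    J = np.stack([c for c in cols], axis=2)
    return jacobian_det(Tensor(J))


def cycle_loss(net_m, net_f, coords) -> Tensor:
    """Symmetric displacement cycle-consistency over a coordinate batch.

    For each x: the forward displacement should be undone by the backward
    network evaluated at the displaced position, and vice versa; squared
    residuals are summed over components and averaged over the batch.
    """
    x = Tensor(np.atleast_2d(np.asarray(coords, dtype=np.float64)))
    dm, _ = net_m.displace_t(x)
    df_at, _ = net_f.displace_t(dm + x)
    r_mf = df_at + dm
    l_mf = (r_mf * r_mf).sum(axis=-1)
    df, _ = net_f.displace_t(x)
    dm_at, _ = net_m.displace_t(df + x)
    r_fm = dm_at + df
    l_fm = (r_fm * r_fm).sum(axis=-1)
    return ((l_mf + l_fm) * 0.5).mean()


def fusion_loss(f_patch, moved_m, moved_fused, window: int = 9) -> Tensor:
    """Mean of the similarity losses of the moved raw and fused images."""
    s1, _, _ = similarity_loss(f_patch, moved_m, window)
    s2, _, _ = similarity_loss(f_patch, moved_fused, window)
    return (s1 + s2) * 0.5


def total_loss(parts: dict, weights: LossWeights, variant: str = "standard"):
    """Weighted total per variant.

    standard: sim + a_reg * reg;  cycle: + a_cyc * cyc;
    fusion: fus + a_reg * reg (the fusion term replaces raw similarity).
    """
    if variant == "fusion":
        total = parts["fusion"] + weights.alpha_reg * parts["regularization"]
    else:
        total = parts["similarity"] + weights.alpha_reg * parts["regularization"]
        if variant == "cycle":
            total = total + weights.alpha_cyc * parts["cycle"]
    return total
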