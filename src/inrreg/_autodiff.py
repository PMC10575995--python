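"""Minimal reverse-mode automatic differentiation on numpy arrays.

The registration losses need gradients with respect to network weights of
expressions that already contain first derivatives of the network with
respect to its input coordinates (the Jacobian-determinant regularizer).
The model code therefore propagates the input-Jacobian *forward* through
ordinary engine operations, so that a single reverse sweep over this tape
yields the weight gradients of every loss term.

Only the operations the package actually uses are implemented.  All arrays
are float64; ``matmul`` supports an arbitrarily batched left operand against
a 2-D weight matrix, which is the only contraction the MLP needs.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "trilinear_sample", "box_sum3", "AdamW"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes that were prepended
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A node in the autodiff tape wrapping a float64 numpy array."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float64)
        self.data = data
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # -- autodiff -------------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        if isinstance(other, (int, float)):  # keep python scalars from
            a = self.data                    # promoting float32 to float64
            return Tensor(a + other, parents=(self,), backward=lambda g: (g,))
        other = Tensor.as_tensor(other)
        out_data = self.data + other.data
        return Tensor(
            out_data,
            parents=(self, other),
            backward=lambda g: (
                _unbroadcast(g, self.data.shape),
                _unbroadcast(g, other.data.shape),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=(self,), backward=lambda g: (-g,))

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        if isinstance(other, (int, float)):
            return (-self) + other
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            a = self.data
            return Tensor(a * other, parents=(self,),
                          backward=lambda g: (g * other,))
        other = Tensor.as_tensor(other)
        a, b = self.data, other.data
        return Tensor(
            a * b,
            parents=(self, other),
            backward=lambda g: (
                _unbroadcast(g * b, a.shape),
                _unbroadcast(g * a, b.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = Tensor.as_tensor(other)
        a, b = self.data, other.data
        return Tensor(
            a / b,
            parents=(self, other),
            backward=lambda g: (
                _unbroadcast(g / b, a.shape),
                _unbroadcast(-g * a / (b * b), b.shape),
            ),
        )

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, p: float):
        a = self.data
        return Tensor(
            a**p, parents=(self,), backward=lambda g: (g * p * a ** (p - 1),)
        )

    def __matmul__(self, other):
        """Batched (..., n, k) @ (k, m) contraction with a 2-D weight matrix."""
        other = Tensor.as_tensor(other)
        a, b = self.data, other.data
        if b.ndim != 2:
            raise ValueError("matmul right operand must be 2-D")
        out = a @ b

        def backward(g):
            ga = g @ b.T
            gb = a.reshape(-1, a.shape[-1]).T @ g.reshape(-1, g.shape[-1])
            return ga, gb

        return Tensor(out, parents=(self, other), backward=backward)

    def __getitem__(self, idx):
        a = self.data
        out = a[idx]

        def backward(g):
            ga = np.zeros_like(a)
            np.add.at(ga, idx, g)
            return (ga,)

        return Tensor(out, parents=(self,), backward=backward)

    # -- elementwise functions ------------------------------------------------
    def sin(self):
        a = self.data
        return Tensor(np.sin(a), parents=(self,), backward=lambda g: (g * np.cos(a),))

    def cos(self):
        a = self.data
        return Tensor(np.cos(a), parents=(self,), backward=lambda g: (-g * np.sin(a),))

    def tanh(self):
        t = np.tanh(self.data)
        return Tensor(t, parents=(self,), backward=lambda g: (g * (1.0 - t * t),))

    def exp(self):
        e = np.exp(self.data)
        return Tensor(e, parents=(self,), backward=lambda g: (g * e,))

    def sqrt(self):
        s = np.sqrt(self.data)
        return Tensor(s, parents=(self,), backward=lambda g: (g * 0.5 / s,))

    def relu(self):
        a = self.data
        mask = a > 0
        return Tensor(
            np.where(mask, a, 0.0), parents=(self,), backward=lambda g: (g * mask,)
        )

    def abs(self):
        a = self.data
        s = np.sign(a)
        return Tensor(np.abs(a), parents=(self,), backward=lambda g: (g * s,))

    # -- reductions and shape -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self.data

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, a.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, a.shape).copy(),)

        return Tensor(
            a.sum(axis=axis, keepdims=keepdims), parents=(self,), backward=backward
        )

    def mean(self, axis=None, keepdims: bool = False):
        a = self.data
        n = a.size if axis is None else np.prod(
            [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        a = self.data
        return Tensor(
            a.reshape(*shape), parents=(self,), backward=lambda g: (g.reshape(a.shape),)
        )

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return Tensor(
            self.data.transpose(*axes),
            parents=(self,),
            backward=lambda g: (g.transpose(*inv),),
        )


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors), backward=backward)


def trilinear_sample(image: np.ndarray, coords: Tensor) -> Tensor:
    """Differentiable trilinear interpolation of a 3-D image.

    ``coords`` holds voxel-index coordinates of shape (N, 3).  Out-of-range
    positions are clamped to the image border (border replication), matching
    the non-differentiable volume warper.  The image itself is a constant;
    gradients flow only to the coordinates.
    """
    image = np.asarray(image)
    if not np.issubdtype(image.dtype, np.floating):
        image = image.astype(np.float64)
    c = coords.data
    shp = np.asarray(image.shape, dtype=c.dtype)
    cc = np.clip(c, 0.0, shp - 1.0)
    i0 = np.floor(cc).astype(np.int64)
    i0 = np.minimum(i0, (np.asarray(image.shape) - 2).clip(min=0))
    f = (cc - i0).astype(c.dtype)  # fractional part in [0, 1]
    x0, y0, z0 = i0[:, 0], i0[:, 1], i0[:, 2]
    x1 = np.minimum(x0 + 1, image.shape[0] - 1)
    y1 = np.minimum(y0 + 1, image.shape[1] - 1)
    z1 = np.minimum(z0 + 1, image.shape[2] - 1)
    fx, fy, fz = f[:, 0], f[:, 1], f[:, 2]
    gx, gy, gz = 1.0 - fx, 1.0 - fy, 1.0 - fz

    v000 = image[x0, y0, z0]
    v001 = image[x0, y0, z1]
    v010 = image[x0, y1, z0]
    v011 = image[x0, y1, z1]
    v100 = image[x1, y0, z0]
    v101 = image[x1, y0, z1]
    v110 = image[x1, y1, z0]
    v111 = image[x1, y1, z1]

    out = (
        v000 * gx * gy * gz
        + v001 * gx * gy * fz
        + v010 * gx * fy * gz
        + v011 * gx * fy * fz
        + v100 * fx * gy * gz
        + v101 * fx * gy * fz
        + v110 * fx * fy * gz
        + v111 * fx * fy * fz
    )

    # derivative is zero where the raw coordinate was clamped
    inside = ((c > 0.0) & (c < shp - 1.0)).astype(c.dtype)

    def backward(g):
        dx = (
            (v100 - v000) * gy * gz
            + (v101 - v001) * gy * fz
            + (v110 - v010) * fy * gz
            + (v111 - v011) * fy * fz
        )
        dy = (
            (v010 - v000) * gx * gz
            + (v011 - v001) * gx * fz
            + (v110 - v100) * fx * gz
            + (v111 - v101) * fx * fz
        )
        dz = (
            (v001 - v000) * gx * gy
            + (v011 - v010) * gx * fy
            + (v101 - v100) * fx * gy
            + (v111 - v110) * fx * fy
        )
        grad_c = np.stack([dx, dy, dz], axis=1) * inside * g[:, None]
        return (grad_c,)

    return Tensor(out, parents=(coords,), backward=backward)


def _valid_box_sum(a: np.ndarray, w: int) -> np.ndarray:
    """Sum over every w^3 window (valid positions) via cumulative sums."""
    out = a
    for axis in range(3):
        cs = np.cumsum(out, axis=axis)
        pad_shape = list(cs.shape)
        pad_shape[axis] = 1
        cs = np.concatenate([np.zeros(pad_shape, dtype=cs.dtype), cs], axis=axis)
        hi = [slice(None)] * 3
        lo = [slice(None)] * 3
        hi[axis] = slice(w, cs.shape[axis])
        lo[axis] = slice(0, cs.shape[axis] - w)
        out = cs[tuple(hi)] - cs[tuple(lo)]
    return out


def box_sum3(x: Tensor, w: int) -> Tensor:
    """Differentiable valid-mode w x w x w box sum of a 3-D tensor."""
    a = x.data
    if any(s < w for s in a.shape):
        raise ValueError(f"window {w} exceeds array shape {a.shape}")
    out = _valid_box_sum(a, w)

    def backward(g):
        # adjoint: each voxel accumulates the gradients of all windows
        # containing it == valid box sum of the zero-padded gradient
        gp = np.pad(g, w - 1)
        return (_valid_box_sum(gp, w),)

    return Tensor(out, parents=(x,), backward=backward)


class AdamW:
    """AdamW optimizer (decoupled weight decay) over a list of Tensors."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (
                (m / b1t) / (np.sqrt(v / b2t) + self.eps)
                + self.weight_decay * p.data
            )
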