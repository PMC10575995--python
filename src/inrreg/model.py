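"""Coordinate networks representing deformation fields, and their variants.

A single MLP maps a normalized coordinate x in [-1, 1]^3 (after Fourier
encoding) to a displacement vector dx, so Phi(x) = x + dx defines the
transformation.  The encoded coordinates are concatenated once more at the
middle hidden layer (a residual/skip connection), and the last linear layer
starts near zero so the initial field is close to the identity.

Variants wrap the same interface:

* :class:`EnsembleModel` averages three networks with different omega.
* :class:`AffineModel` adds a trainable global affine map, Phi(x) = A x + t + dx.
* :class:`CascadeModel` adds a trainable correction to a frozen first-stage
  field, Phi_C(x) = Phi_1(x) + dx'.

Every model exposes ``displace_t(coords, with_jac)`` returning engine
tensors (displacement, and optionally its input-Jacobian with layout
``J[n, i, j] = d dx_j / d x_i``), plus numpy conveniences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ._autodiff import Tensor, concat
from .activations import ActivationSpec, apply_activation, init_layer, layer_omega
from .coords import encoding_length, fourier_encode_t, normalize_grid

__all__ = [
    "NetworkConfig",
    "InrNetwork",
    "EnsembleModel",
    "AffineModel",
    "CascadeModel",
    "build_network",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class NetworkConfig:
    hidden_layers: int = 5
    width: int = 256
    activation: ActivationSpec = field(default_factory=ActivationSpec)
    n_freq: int = 6
    freq_base: float = float(np.pi)  # 2^k * pi encoding frequencies
    skip_at_middle: bool = True
    out_dim: int = 3
    seed: int = 0
    dtype: str = "float64"  # float32 roughly halves CPU training time

    def __post_init__(self):
        if self.hidden_layers < 1 or self.width < 1:
            raise ValueError("hidden_layers and width must be >= 1")
        if isinstance(self.activation, dict):
            self.activation = ActivationSpec.from_dict(self.activation)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["activation"] = self.activation.to_dict()
        return d


class InrNetwork:
    """The coordinate MLP F_psi with optional input-Jacobian propagation."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        self.dtype = np.dtype(config.dtype)
        spec = config.activation
        rng = np.random.default_rng(config.seed)
        enc_len = encoding_length(config.n_freq)
        self.middle = config.hidden_layers // 2 if config.skip_at_middle else -1

        self.weights, self.biases = [], []
        fan_in = enc_len
        for layer in range(config.hidden_layers):
            if layer == self.middle and layer > 0:
                fan_in += enc_len
            w, b = init_layer(fan_in, config.width, spec,
                              is_first=(layer == 0), rng=rng)
            self.weights.append(Tensor(w.astype(self.dtype), requires_grad=True))
            self.biases.append(Tensor(b.astype(self.dtype), requires_grad=True))
            fan_in = config.width
        w, b = init_layer(fan_in, config.out_dim, spec, is_last=True, rng=rng)
        self.weights.append(Tensor(w.astype(self.dtype), requires_grad=True))
        self.biases.append(Tensor(b.astype(self.dtype), requires_grad=True))

        self.attn_params = None
        if spec.name == "sine_attention":
            # (a, b) scaling scalars per hidden layer, started at (1, 0)
            one = np.asarray(1.0, dtype=self.dtype)
            zero = np.asarray(0.0, dtype=self.dtype)
            self.attn_params = [
                (Tensor(one.copy(), requires_grad=True),
                 Tensor(zero.copy(), requires_grad=True))
                for _ in range(config.hidden_layers)
            ]
        self.omega_t = None
        if spec.trainable_omega:
            self.omega_t = Tensor(np.asarray(spec.omega, dtype=self.dtype),
                                  requires_grad=True)

    # -- parameters -----------------------------------------------------------
    def parameters(self):
        params = list(self.weights) + list(self.biases)
        if self.attn_params is not None:
            for a, b in self.attn_params:
                params.extend((a, b))
        if self.omega_t is not None:
            params.append(self.omega_t)
        return params

    def freeze(self) -> None:
        for p in self.parameters():
            p.requires_grad = False

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- forward --------------------------------------------------------------
    def displace_t(self, coords, with_jac: bool = False, J0=None):
        """Engine forward pass.

        ``coords`` is a Tensor or array (N, 3).  Returns ``(dx, J)`` where
        ``J[n, i, j] = d dx_j / d x_i`` (None unless ``with_jac``).
        """
        cfg = self.config
        spec = cfg.activation
        if not isinstance(coords, Tensor):
            coords = np.asarray(coords, dtype=self.dtype)
        x = Tensor.as_tensor(coords)
        enc, Jenc = fourier_encode_t(x, cfg.n_freq, cfg.freq_base,
                                     with_jac=with_jac, J0=J0)
        h, Jh = enc, Jenc
        for layer in range(cfg.hidden_layers):
            if layer == self.middle and layer > 0:
                h = concat([h, enc], axis=-1)
                if with_jac:
                    Jh = concat([Jh, Jenc], axis=-1)
            z = h @ self.weights[layer] + self.biases[layer]
            Jz = None if Jh is None else Jh @ self.weights[layer]
            omega = self.omega_t
            if omega is None:
                omega = layer_omega(spec, cfg.width)
                if isinstance(omega, np.ndarray):
                    omega = omega.astype(self.dtype)
            attn = self.attn_params[layer] if self.attn_params else None
            h, Jh = apply_activation(z, Jz, spec, omega, attn)
        dx = h @ self.weights[-1] + self.biases[-1]
        J = None if Jh is None else Jh @ self.weights[-1]
        return dx, J

    # -- numpy conveniences ---------------------------------------------------
    def displacement(self, points: np.ndarray, chunk: int = 65536) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=self.dtype))
        out = np.empty((points.shape[0], self.config.out_dim))
        for lo in range(0, points.shape[0], chunk):
            dx, _ = self.displace_t(points[lo:lo + chunk])
            out[lo:lo + chunk] = dx.data
        return out

    def deform(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return points + self.displacement(points)

    def jacobian_of_phi(self, points: np.ndarray) -> np.ndarray:
        """Dense Jacobian dPhi_i/dx_j (N, 3, 3) by automatic differentiation."""
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        _, J = self.displace_t(points, with_jac=True)
        return np.eye(3)[None] + np.swapaxes(J.data, 1, 2)

    def dense_field(self, shape, chunk: int = 65536) -> np.ndarray:
        grid = normalize_grid(shape)
        return self.displacement(grid.points, chunk=chunk).reshape(*shape, 3)


def build_network(config: NetworkConfig) -> InrNetwork:
    return InrNetwork(config)


class EnsembleModel:
    """Mean displacement of several jointly trained coordinate networks."""

    def __init__(self, networks):
        if len(networks) < 2:
            raise ValueError("an ensemble needs at least two member networks")
        if any(n.config.out_dim != networks[0].config.out_dim for n in networks):
            raise ValueError("ensemble members must share out_dim")
        self.networks = list(networks)
        self.omegas = [n.config.activation.omega for n in networks]
        self.dtype = networks[0].dtype

    @classmethod
    def siren_trio(cls, base: NetworkConfig, omegas=(10.0, 30.0, 50.0)):
        members = []
        for i, om in enumerate(omegas):
            act = ActivationSpec.from_dict({**base.activation.to_dict(), "omega": om})
            cfg = NetworkConfig(**{**base.to_dict(), "activation": act,
                                   "seed": base.seed + i})
            members.append(InrNetwork(cfg))
        return cls(members)

    def parameters(self):
        return [p for n in self.networks for p in n.parameters()]

    def displace_t(self, coords, with_jac: bool = False):
        outs = [n.displace_t(coords, with_jac=with_jac) for n in self.networks]
        k = 1.0 / len(outs)
        dx = outs[0][0] * k
        for d, _ in outs[1:]:
            dx = dx + d * k
        J = None
        if with_jac:
            J = outs[0][1] * k
            for _, j in outs[1:]:
                J = J + j * k
        return dx, J

    def displacement(self, points, chunk: int = 65536):
        return np.mean([n.displacement(points, chunk) for n in self.networks], axis=0)

    def dense_field(self, shape, chunk: int = 65536):
        return self.displacement(normalize_grid(shape).points, chunk).reshape(*shape, 3)


class AffineModel:
    """Global affine composed additively with the local field (12 dof).

    Phi_A(x) = A x + t + dx(x); A starts at the identity and t at zero, so
    the initial map is near-identity.
    """

    def __init__(self, network: InrNetwork):
        self.network = network
        dt = getattr(network, "dtype", np.float64)
        self.dtype = dt
        self.A = Tensor(np.eye(3, dtype=dt), requires_grad=True)
        self.t = Tensor(np.zeros(3, dtype=dt), requires_grad=True)

    def parameters(self):
        return self.network.parameters() + [self.A, self.t]

    def displace_t(self, coords, with_jac: bool = False):
        x = Tensor.as_tensor(coords)
        dx, J = self.network.displace_t(x, with_jac=with_jac)
        eye = np.eye(3, dtype=self.A.data.dtype)
        aff = x @ (self.A - eye).transpose(1, 0) + self.t
        dx = dx + aff
        if with_jac:
            J = J + (self.A - eye).transpose(1, 0)
        return dx, J

    def displacement(self, points, chunk: int = 65536):
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        local = self.network.displacement(points, chunk)
        return local + points @ (self.A.data - np.eye(3)).T + self.t.data

    def dense_field(self, shape, chunk: int = 65536):
        return self.displacement(normalize_grid(shape).points, chunk).reshape(*shape, 3)


class CascadeModel:
    """Additive two-stage field Phi_C(x) = Phi_1(x) + dx'(x).

    The first stage is frozen; only the correction network trains.  By
    default the correction network reads the original coordinate x (the
    literal additive form); ``composed=True`` feeds it Phi_1(x) instead.
    """

    def __init__(self, stage1, stage2: InrNetwork, composed: bool = False):
        self.stage1 = stage1
        self.stage2 = stage2
        self.composed = composed
        self.dtype = stage2.dtype
        if hasattr(stage1, "freeze"):
            stage1.freeze()

    def parameters(self):
        return self.stage2.parameters()

    def _stage1_const(self, points, with_jac):
        """Frozen stage-1 displacement (and Jacobian) as constants."""
        if isinstance(self.stage1, (InrNetwork, EnsembleModel, AffineModel)):
            dx, J = self.stage1.displace_t(points, with_jac=with_jac)
            return dx.data, (None if J is None else J.data)
        disp = self.stage1.displacement(points)  # analytic field
        J = None
        if with_jac:
            J = np.swapaxes(self.stage1.jacobian(points), 1, 2) - np.eye(3)[None]
        return disp, J

    def displace_t(self, coords, with_jac: bool = False):
        points = coords.data if isinstance(coords, Tensor) else np.asarray(coords)
        d1, J1 = self._stage1_const(points, with_jac or self.composed)
        if self.composed:
            phi1 = Tensor(points + d1)
            J0 = Tensor(np.eye(3)[None] + J1)
            dx2, J2 = self.stage2.displace_t(phi1, with_jac=with_jac, J0=J0)
        else:
            dx2, J2 = self.stage2.displace_t(coords, with_jac=with_jac)
        dx = dx2 + d1
        J = None
        if with_jac:
            J = J2 + J1
        return dx, J

    def displacement(self, points, chunk: int = 65536):
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        d1, _ = self._stage1_const(points, False)
        if self.composed:
            return d1 + self.stage2.displacement(points + d1, chunk)
        return d1 + self.stage2.displacement(points, chunk)

    def dense_field(self, shape, chunk: int = 65536):
        return self.displacement(normalize_grid(shape).points, chunk).reshape(*shape, 3)


# -- checkpointing ------------------------------------------------------------

def save_checkpoint(net: InrNetwork, path) -> None:
    """Save weights plus the self-describing NetworkConfig (npz + json)."""
    arrays = {f"w{i}": w.data for i, w in enumerate(net.weights)}
    arrays.update({f"b{i}": b.data for i, b in enumerate(net.biases)})
    if net.omega_t is not None:
        arrays["omega"] = net.omega_t.data
    if net.attn_params is not None:
        for i, (a, b) in enumerate(net.attn_params):
            arrays[f"attn_a{i}"], arrays[f"attn_b{i}"] = a.data, b.data
    arrays["config_json"] = np.frombuffer(
        json.dumps(net.config.to_dict()).encode(), dtype=np.uint8
    )
    np.savez(str(path), **arrays)


def load_checkpoint(path) -> InrNetwork:
    data = np.load(str(path))
    config = NetworkConfig(**json.loads(bytes(data["config_json"]).decode()))
    net = InrNetwork(config)
    for i in range(len(net.weights)):
        net.weights[i].data = data[f"w{i}"]
        net.biases[i].data = data[f"b{i}"]
    if net.omega_t is not None:
        net.omega_t.data = data["omega"]
    if net.attn_params is not None:
        for i, (a, b) in enumerate(net.attn_params):
            a.data, b.data = data[f"attn_a{i}"], data[f"attn_b{i}"]
    return net
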