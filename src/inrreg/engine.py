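"""Per-pair optimization: the training loop and its variants.

Each registration trains a coordinate network from scratch for one
moving/fixed pair.  Per step, one random cubic patch is drawn, the
deformation is evaluated at the patch's voxel coordinates, the moving image
is sampled at the deformed positions by differentiable trilinear
interpolation, and the similarity (NCC + local NCC) plus the Jacobian
regularizer — evaluated at the same coordinates — are backpropagated
through one AdamW step.  An epoch is a fixed number of patches regardless
of image size; no early stopping is applied.

Variants: plain (any activation), trainable/width-modulated/attention
omega (via the activation spec), global affine composition, three-network
ensemble, two-stage cascade, symmetric cycle-consistent pair, and
registration-guided fusion.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field as dc_field, asdict
from typing import Optional

import numpy as np

from ._autodiff import AdamW, Tensor, trilinear_sample
from .coords import PatchSpec, patch_coords, sample_patches
from .fusion import make_channels, simplex_weights
from .image_io import Volume
from .losses import (LossReport, LossWeights, cycle_loss, jacobian_det,
                     similarity_loss, total_loss)
from .metrics import folding_percentage
from .model import (AffineModel, CascadeModel, EnsembleModel, InrNetwork,
                    NetworkConfig)
from .warp import apply_field

__all__ = [
    "TrainConfig",
    "RegistrationResult",
    "register",
    "register_cycle",
    "register_cascade",
    "register_fusion",
    "hyperparameter_sweep",
]


@dataclass
class TrainConfig:
    epochs: int = 40
    patches_per_epoch: int = 500
    patch_size: int = 32
    learning_rate: float = 1e-4
    weight_decay: float = 0.01
    lncc_window: int = 9
    weights: LossWeights = dc_field(default_factory=LossWeights)
    network: NetworkConfig = dc_field(default_factory=NetworkConfig)
    variant: str = "standard"  # standard | affine | ensemble
    ensemble_omegas: tuple = (10.0, 30.0, 50.0)
    normalize_intensity: bool = True
    seed: int = 0  # sampler seed; the network seed lives in `network`

    def __post_init__(self):
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.lncc_window > self.patch_size:
            raise ValueError("lncc_window must not exceed patch_size")
        if isinstance(self.weights, dict):
            self.weights = LossWeights(**self.weights)
        if isinstance(self.network, dict):
            self.network = NetworkConfig(**self.network)

    def echo(self) -> dict:
        d = asdict(self)
        d["network"] = self.network.to_dict()
        return d


@dataclass
class RegistrationResult:
    model: object
    field: np.ndarray          # dense displacement (X, Y, Z, 3), normalized units
    moved: Volume
    history: list              # per-epoch LossReport
    config: dict
    fusion_outputs: Optional[dict] = None
    seconds: float = 0.0

    def folding_pct(self) -> float:
        return folding_percentage(self.field)


def _prepare(moving, fixed, config: TrainConfig):
    moving = moving if isinstance(moving, Volume) else Volume(np.asarray(moving))
    fixed = fixed if isinstance(fixed, Volume) else Volume(np.asarray(fixed))
    if moving.shape != fixed.shape:
        raise ValueError(f"image shapes differ: {moving.shape} vs {fixed.shape}"
                         " (resample onto a common grid first)")
    if config.patch_size > min(moving.shape):
        raise ValueError("patch_size exceeds the volume")
    if config.normalize_intensity:
        moving, fixed = moving.normalized(), fixed.normalized()
    return moving, fixed


def _build_model(config: TrainConfig):
    if config.variant == "affine":
        return AffineModel(InrNetwork(config.network))
    if config.variant == "ensemble":
        return EnsembleModel.siren_trio(config.network, config.ensemble_omegas)
    return InrNetwork(config.network)


def _sample_at(volume_values, phi: Tensor, shape):
    """Differentiable sampling of a volume at deformed normalized coords."""
    scale = (np.asarray(shape, dtype=phi.data.dtype) - 1.0) * 0.5
    idx = phi * scale + scale
    return trilinear_sample(volume_values, idx)


def _model_dtype(model):
    return getattr(model, "dtype", np.float64)


def _finalize(model, moving, fixed, config, history, t0, fusion_outputs=None):
    dense = model.dense_field(moving.shape)
    moved = apply_field(moving, dense)
    return RegistrationResult(
        model=model, field=dense, moved=moved, history=history,
        config=config.echo(), fusion_outputs=fusion_outputs,
        seconds=time.perf_counter() - t0,
    )


def register(moving, fixed, config: TrainConfig, model=None,
             epoch_callback=None) -> RegistrationResult:
    """Standard per-pair registration (Eq-1-style loss).

    ``model`` may be passed to continue training an existing model (used by
    the cascade); ``epoch_callback(epoch, model)`` supports trajectory
    logging in sweeps.
    """
    t0 = time.perf_counter()
    moving, fixed = _prepare(moving, fixed, config)
    if model is None:
        model = _build_model(config)
    opt = AdamW(model.parameters(), lr=config.learning_rate,
                weight_decay=config.weight_decay)
    corners = sample_patches(
        moving.shape,
        PatchSpec(config.patch_size, config.epochs * config.patches_per_epoch,
                  config.seed),
    )
    dt = _model_dtype(model)
    mov, fix = moving.values.astype(dt), fixed.values.astype(dt)
    ps, w = config.patch_size, config.lncc_window
    history = []
    step = 0
    for epoch in range(config.epochs):
        acc = np.zeros(4)
        for _ in range(config.patches_per_epoch):
            corner = corners[step]
            step += 1
            coords = patch_coords(corner, ps, moving.shape).astype(dt)
            dx, J = model.displace_t(coords, with_jac=True)
            phi = dx + coords
            moved = _sample_at(mov, phi, moving.shape).reshape(ps, ps, ps)
            fpatch = fix[corner[0]:corner[0] + ps,
                         corner[1]:corner[1] + ps,
                         corner[2]:corner[2] + ps]
            sim, nccv, lnccv = similarity_loss(fpatch, moved, w)
            reg = (1.0 - jacobian_det(J)).abs().mean()
            total = total_loss({"similarity": sim, "regularization": reg},
                               config.weights)
            if not np.isfinite(total.item()):
                raise FloatingPointError(
                    f"non-finite loss at step {step}, patch corner {tuple(corner)}"
                )
            opt.zero_grad()
            total.backward()
            opt.step()
            acc += (sim.item(), nccv.item(), lnccv.item(), reg.item())
        acc /= config.patches_per_epoch
        history.append(LossReport(
            similarity=acc[0], ncc=acc[1], lncc=acc[2], regularization=acc[3],
            total=acc[0] + config.weights.alpha_reg * acc[3],
        ))
        if epoch_callback is not None:
            epoch_callback(epoch, model)
    return _finalize(model, moving, fixed, config, history, t0)


def register_cycle(moving, fixed, config: TrainConfig):
    """Jointly train forward (M->F) and backward (F->M) networks.

    Each step shares one coordinate patch between the directions; the total
    is the sum of both directions' similarity+regularization losses plus
    alpha_cyc times the symmetric displacement cycle-consistency term.
    Returns ``(result_mf, result_fm)``.
    """
    t0 = time.perf_counter()
    moving, fixed = _prepare(moving, fixed, config)
    net_m = InrNetwork(config.network)
    cfg_f = NetworkConfig(**{**config.network.to_dict(),
                             "seed": config.network.seed + 1})
    net_f = InrNetwork(cfg_f)
    opt = AdamW(net_m.parameters() + net_f.parameters(),
                lr=config.learning_rate, weight_decay=config.weight_decay)
    corners = sample_patches(
        moving.shape,
        PatchSpec(config.patch_size, config.epochs * config.patches_per_epoch,
                  config.seed),
    )
    dt = _model_dtype(net_m)
    mov, fix = moving.values.astype(dt), fixed.values.astype(dt)
    ps, w = config.patch_size, config.lncc_window
    hist_m, hist_f = [], []
    step = 0
    for _epoch in range(config.epochs):
        acc_m, acc_f, acc_c = np.zeros(2), np.zeros(2), 0.0
        for _ in range(config.patches_per_epoch):
            corner = corners[step]
            step += 1
            coords = patch_coords(corner, ps, moving.shape).astype(dt)
            fpatch = fix[corner[0]:corner[0] + ps, corner[1]:corner[1] + ps,
                         corner[2]:corner[2] + ps]
            mpatch = mov[corner[0]:corner[0] + ps, corner[1]:corner[1] + ps,
                         corner[2]:corner[2] + ps]

            dx_m, J_m = net_m.displace_t(coords, with_jac=True)
            moved_m = _sample_at(mov, dx_m + coords, moving.shape).reshape(ps, ps, ps)
            sim_m, _, _ = similarity_loss(fpatch, moved_m, w)
            reg_m = (1.0 - jacobian_det(J_m)).abs().mean()

            dx_f, J_f = net_f.displace_t(coords, with_jac=True)
            moved_f = _sample_at(fix, dx_f + coords, moving.shape).reshape(ps, ps, ps)
            sim_f, _, _ = similarity_loss(mpatch, moved_f, w)
            reg_f = (1.0 - jacobian_det(J_f)).abs().mean()

            cyc = cycle_loss(net_m, net_f, coords)
            total = (sim_m + sim_f
                     + config.weights.alpha_reg * (reg_m + reg_f)
                     + config.weights.alpha_cyc * cyc)
            if not np.isfinite(total.item()):
                raise FloatingPointError(
                    f"non-finite loss at step {step}, patch corner {tuple(corner)}"
                )
            opt.zero_grad()
            total.backward()
            opt.step()
            acc_m += (sim_m.item(), reg_m.item())
            acc_f += (sim_f.item(), reg_f.item())
            acc_c += cyc.item()
        n = config.patches_per_epoch
        acc_m, acc_f, acc_c = acc_m / n, acc_f / n, acc_c / n
        hist_m.append(LossReport(similarity=acc_m[0], regularization=acc_m[1],
                                 cycle=acc_c,
                                 total=acc_m[0] + config.weights.alpha_reg * acc_m[1]
                                 + config.weights.alpha_cyc * acc_c))
        hist_f.append(LossReport(similarity=acc_f[0], regularization=acc_f[1],
                                 cycle=acc_c,
                                 total=acc_f[0] + config.weights.alpha_reg * acc_f[1]
                                 + config.weights.alpha_cyc * acc_c))
    res_m = _finalize(net_m, moving, fixed, config, hist_m, t0)
    res_f = _finalize(net_f, fixed, moving, config, hist_f, t0)
    return res_m, res_f


def register_cascade(moving, fixed, config1: TrainConfig,
                     config2: TrainConfig, composed: bool = False):
    """Two-stage cascade: train, freeze, then train an additive correction.

    With zero stage-2 epochs the stage-1 result is returned unchanged (no
    correction was trained).  ``config2.weights.alpha_reg`` is typically 0.1
    or 1; the regularizer in stage 2 acts on the composite field.
    """
    result1 = register(moving, fixed, config1)
    if config2.epochs == 0:
        return result1
    net2 = InrNetwork(config2.network)
    cascade = CascadeModel(result1.model, net2, composed=composed)
    result = register(moving, fixed, config2, model=cascade)
    result.config["stage1"] = result1.config
    return result


def register_fusion(moving, fixed, config: TrainConfig,
                    frozen_weights=None, foreground_threshold: float = 0.1):
    """Joint registration and image fusion.

    A second sine (omega=30) coordinate network outputs 3 logits mapped to
    the simplex; the moved fused image mixes the raw, Laplacian and
    Gaussian channels sampled at the deformed coordinates with weights
    evaluated at the patch coordinates.  ``frozen_weights`` fixes the
    weights to a constant simplex point (no fusion network is trained),
    which with (1, 0, 0) reduces exactly to plain registration.
    """
    t0 = time.perf_counter()
    moving, fixed = _prepare(moving, fixed, config)
    model = _build_model(config)
    channels = make_channels(moving)
    ch_grid = channels.stack()  # (X, Y, Z, 3)
    fusion_net = None
    params = model.parameters()
    if frozen_weights is None:
        fus_cfg = NetworkConfig(**{**config.network.to_dict(),
                                   "seed": config.network.seed + 101})
        fus_cfg.activation = type(config.network.activation)(name="sine", omega=30.0)
        fusion_net = InrNetwork(fus_cfg)
        params = params + fusion_net.parameters()
    else:
        frozen_weights = np.asarray(frozen_weights, dtype=np.float64)
    opt = AdamW(params, lr=config.learning_rate, weight_decay=config.weight_decay)
    corners = sample_patches(
        moving.shape,
        PatchSpec(config.patch_size, config.epochs * config.patches_per_epoch,
                  config.seed),
    )
    dt = _model_dtype(model)
    mov, fix = moving.values.astype(dt), fixed.values.astype(dt)
    ch_grid = ch_grid.astype(dt)
    ps, w = config.patch_size, config.lncc_window
    history = []
    step = 0
    for _epoch in range(config.epochs):
        acc = np.zeros(3)
        for _ in range(config.patches_per_epoch):
            corner = corners[step]
            step += 1
            coords = patch_coords(corner, ps, moving.shape).astype(dt)
            dx, J = model.displace_t(coords, with_jac=True)
            phi = dx + coords
            moved_m = _sample_at(mov, phi, moving.shape).reshape(ps, ps, ps)
            sampled = [
                _sample_at(ch_grid[..., c], phi, moving.shape) for c in range(3)
            ]
            if fusion_net is not None:
                logits, _ = fusion_net.displace_t(coords)
                weights = simplex_weights(logits)
                moved_fused = (weights[:, 0] * sampled[0]
                               + weights[:, 1] * sampled[1]
                               + weights[:, 2] * sampled[2]).reshape(ps, ps, ps)
            else:
                moved_fused = (frozen_weights[0] * sampled[0]
                               + frozen_weights[1] * sampled[1]
                               + frozen_weights[2] * sampled[2]).reshape(ps, ps, ps)
            fpatch = fix[corner[0]:corner[0] + ps, corner[1]:corner[1] + ps,
                         corner[2]:corner[2] + ps]
            sim_raw, _, _ = similarity_loss(fpatch, moved_m, w)
            sim_fused, _, _ = similarity_loss(fpatch, moved_fused, w)
            fus = (sim_raw + sim_fused) * 0.5
            reg = (1.0 - jacobian_det(J)).abs().mean()
            total = total_loss({"fusion": fus, "regularization": reg},
                               config.weights, variant="fusion")
            if not np.isfinite(total.item()):
                raise FloatingPointError(
                    f"non-finite loss at step {step}, patch corner {tuple(corner)}"
                )
            opt.zero_grad()
            total.backward()
            opt.step()
            acc += (sim_raw.item(), fus.item(), reg.item())
        acc /= config.patches_per_epoch
        history.append(LossReport(
            similarity=acc[0], fusion=acc[1], regularization=acc[2],
            total=acc[1] + config.weights.alpha_reg * acc[2],
        ))
    # dense fusion outputs
    from .coords import normalize_grid
    grid = normalize_grid(moving.shape)
    if fusion_net is not None:
        logits = fusion_net.displacement(grid.points)
        wdense = simplex_weights(Tensor(logits)).data.reshape(*moving.shape, 3)
    else:
        wdense = np.broadcast_to(frozen_weights, (*moving.shape, 3)).copy()
    fused = (ch_grid * wdense).sum(axis=-1)
    mask = moving.values > foreground_threshold
    mean_w = (wdense[mask].mean(axis=0) if mask.any()
              else wdense.reshape(-1, 3).mean(axis=0))
    fusion_outputs = {
        "fusion_net": fusion_net,
        "weights": wdense,
        "fused_image": fused,
        "mean_weights": tuple(round(float(x), 4) for x in mean_w),
    }
    return _finalize(model, moving, fixed, config, history, t0,
                     fusion_outputs=fusion_outputs)


def hyperparameter_sweep(moving, fixed, moving_labels, fixed_labels,
                         config: TrainConfig,
                         omegas=(10.0, 20.0, 30.0, 40.0, 50.0),
                         alpha_regs=(1.0, 0.1, 0.01),
                         eval_every: int = 1):
    """Grid sweep over (omega, alpha_reg) recording metric trajectories.

    Returns a pandas DataFrame with one row per epoch per grid cell:
    omega, alpha_reg, epoch, dice_avg, dice_min, folding_pct — the raw
    material for convergence/trade-off plots.
    """
    import pandas as pd

    from .metrics import dice_summary
    from .warp import warp_labels

    rows = []
    for om in omegas:
        for ar in alpha_regs:
            act = type(config.network.activation)(
                **{**config.network.activation.to_dict(), "omega": float(om)}
            )
            net_cfg = NetworkConfig(**{**config.network.to_dict(), "activation": act})
            cfg = TrainConfig(**{**asdict(config),
                                 "network": net_cfg,
                                 "weights": LossWeights(alpha_reg=float(ar)),
                                 })

            def log(epoch, model, om=om, ar=ar):
                if (epoch + 1) % eval_every:
                    return
                dense = model.dense_field(np.asarray(moving_labels).shape)
                warped = warp_labels(np.asarray(moving_labels), dense)
                avg, mn, _ = dice_summary(warped, np.asarray(fixed_labels))
                rows.append({"omega": om, "alpha_reg": ar, "epoch": epoch + 1,
                             "dice_avg": avg, "dice_min": mn,
                             "folding_pct": folding_percentage(dense)})

            register(moving, fixed, cfg, epoch_callback=log)
    return pd.DataFrame(rows)
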