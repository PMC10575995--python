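# inrreg

Per-pair deformable 3-D image registration with implicit neural
representations (INRs), aimed at brain MRI but applicable to any pair of
scalar volumes on a common grid.

## The method

Given a moving image *M* and a fixed image *F*, registration seeks a
transformation *T*<sub>Φ</sub> aligning *M* to *F*. Here the deformation
field is represented implicitly: a coordinate MLP 𝓕<sub>ψ</sub> maps each
normalized coordinate x̄ ∈ [−1, 1]³ to a displacement Δx̄, so

  Φ(x̄) = x̄ + Δx̄,  moved image = *M* sampled at Φ(x̄).

The network is trained **from scratch for each image pair** by minimizing

  𝓛 = 𝓛<sub>sim</sub>(F, T<sub>Φ</sub>(M)) + α<sub>reg</sub> 𝓛<sub>reg</sub>(Φ)

where 𝓛<sub>sim</sub> = |1 − NCC| over a sampled 3-D patch plus the mean of
|1 − NCC| over 9×9×9 sliding windows (local NCC), and
𝓛<sub>reg</sub> = mean |1 − |J<sub>Φ</sub>|| penalizes deviation of the
field's Jacobian determinant from 1 (computed by automatic
differentiation). Coordinates are Fourier-encoded with six frequencies; the
encoding is concatenated again at the middle hidden layer; the last linear
layer starts in [−10⁻⁴, 10⁻⁴] so training begins near the identity map.

Implemented components:

* **Activations** — ReLU, sine (SIREN, ω default 30), snake, sine+, chirp,
  Morlet-wavelet imaginary part, plus an attention mechanism that modulates
  ω inside (10, 50) from the layer's mean absolute pre-activation, a
  trainable scalar ω, and per-unit width modulation of ω from 10 to 50.
* **Variants** — global affine composition (Φ = A x̄ + t + Δx̄, 12 extra
  parameters), three-network ensembles (ω ∈ {10, 30, 50}, mean field,
  trained jointly), two-stage cascades (frozen first field plus trained
  additive correction), cycle-consistent forward/backward network pairs
  (displacement cycle residual, weight α<sub>cyc</sub> = 100), and
  registration-guided fusion (a second network predicts per-voxel simplex
  weights over the raw / Laplacian-filtered / Gaussian-filtered moving
  image).
* **Evaluation** — per-region Dice (average and worst region) and field
  folding, the percentage of voxels with non-positive Jacobian determinant.
* **Synthetic data** — multi-region phantoms and analytic displacement
  fields (identity, affine, Gaussian bump, sinusoid) with closed-form
  Jacobians, so every derivative-based loss and metric has an exact oracle.

Everything runs on plain numpy: the package carries a compact tape-based
reverse-mode autodiff core (`inrreg._autodiff`) with an AdamW optimizer,
and propagates the network's input-Jacobian forward through the tape so the
Jacobian regularizer is differentiable with respect to the weights.

## Worked example

```bash
python examples/02_register_pair.py
```

builds a 48³ five-region phantom, deforms it with an analytic folding-free
Gaussian-bump field (amplitude 0.08 normalized units ≈ 1.9 voxels at the
bump center), adds 1% noise, and registers the pair with a sine network:

```
trained 8 epochs x 100 patches in 82s
final similarity loss: 0.0393 (0 = perfect local+global correlation)
mean endpoint error: 0.0032 normalized units = 9.9% of the true mean magnitude
Dice after registration: avg 0.998, worst region 0.994
folding: 0.000% non-positive Jacobian determinants
```

The endpoint error is the voxel-wise distance between recovered and true
displacement; 0 folding means the recovered map is locally invertible
everywhere. The other scripts in `examples/` demonstrate the activation
family, the structural variants, fusion, and the ω sweep.

A thin CLI mirrors the library for shell use:

```bash
inrreg synth --out pair/ --shape 48,48,48
inrreg register --moving pair/moving.nii.gz --fixed pair/fixed.nii.gz \
    --variant siren --omega 30 --alpha-reg 0.1 --epochs 8 \
    --patch-size 16 --patches-per-epoch 100 --out run/
inrreg evaluate --moving-labels pair/moving_labels.nii.gz \
    --fixed-labels pair/fixed_labels.nii.gz --field run/field.nii.gz
```

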