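# Methods

## Model

The deformation field of one moving/fixed volume pair is represented by a
coordinate MLP trained from scratch for that pair. Voxel indices are
mapped to voxel-centered normalized coordinates, index *i* on an axis of
length *d* ↦ 2·i/(d−1) − 1, so the grid spans exactly [−1, 1]³ (axes of
length 1 map to 0). The network input is a Fourier positional encoding
with six power-of-two frequencies,
[x̄, sin(2ᵏπx̄), cos(2ᵏπx̄)]₀≤k<6, applied component-wise (39 features);
whether frequencies are 2ᵏπ or 2ᵏ is a config knob (`freq_base`), with
2ᵏπ the default so the lowest band spans a half period across the volume.
The raw coordinate is kept in the encoding as a low-frequency pathway.

The default backbone has five hidden layers of 256 units; the encoded
coordinates are concatenated once more into the input of the middle hidden
layer (layer 3 of 5 — the unique central layer; feeding several layers is
possible via the code but a single skip is the default). The output layer
has 3 units (displacement) and is initialized uniformly in [−10⁻⁴, 10⁻⁴]
with zero bias, so a fresh network is a near-identity map (empirically
max |Δx̄| < 10⁻³ at init). Sinusoidal layers (sine, chirp, Morlet,
attention) use the SIREN scheme: U(±1/fan_in) at the first layer,
U(±√(6/fan_in)/ω) at hidden layers; chirp/Morlet can instead use the
hidden rule at the first layer (`first_layer_scheme`), since their source
description only says the initialization follows the SIREN recipe.
ReLU/snake/sine+ use Kaiming-style uniform bounds — snake and sine+
contain an identity path, so the ω-scaled bound is unnecessary for
gradient stability. Biases are U(±1/√fan_in) except the zero output bias.

### Activations

| name | σ(x) | notes |
|---|---|---|
| relu | max(0, x) | baseline, no oscillation |
| sine | sin(ωx) | SIREN; ω default 30 |
| snake | x + cos(ωx)/ω + 1/ω | identity + scaled cosine |
| sine+ | x + sin(ωx) | identity + unscaled sine |
| chirp | sin(ωx + a_ω·x·tanh(ωx)) | frequency varies near 0, saturates to ω+a_ω; a_ω default 10 |
| morlet | a_ω e^(−x²/2)(sin(ωx) − b_ω) | Gaussian-windowed sine; a_ω, b_ω closed-form normalizers |

The attention variant makes ω input-dependent per layer:
ω = ω₀ + Δω·tanh(a·mean|xᵢ| + b) with trainable scalars (a, b) initialized
at (1, 0) so ω starts near ω₀ = 30; with Δω = 20 the attainable range is
(10, 50). The trainable-ω variant promotes a single scalar ω (initial 30)
to a parameter of the whole network; width modulation fixes per-unit ω
linearly spaced from 10 to 50 across each layer.

A subtlety worth recording: chirp is **not** an odd function — the term
x·tanh(ωx) is even (odd × odd) — so only sine (exactly) and Morlet (up to
its numerically negligible b_ω offset at ω = 30) satisfy σ(−x) = −σ(x).

## Losses

* Similarity: 𝓛_ncc = |1 − NCC| over the whole sampled patch plus
  𝓛_lncc, the mean of |1 − NCC| over 9³ sliding windows (stride 1, valid
  windows only — padded windows would mix border-clamped content into the
  statistic; the stride is exposed in config). Both denominators carry
  ε = 10⁻⁵ inside the square root to guard constant (background) windows
  without biasing informative ones. Local sums use cumulative-sum box
  filters; the unit tests pin them to a naive per-window loop at 10⁻⁶.
* Regularizer: mean |1 − |J_Φ|| over the same coordinates as the
  similarity patch, with J_Φ from automatic differentiation (the
  input-Jacobian is propagated forward through the tape, so the penalty is
  differentiable w.r.t. the weights). The determinant is signed: the
  penalty itself does not forbid negative determinants, which is why
  folding is reported as a separate metric.
* Cycle consistency: with forward/backward networks 𝓕_M, 𝓕_F, the
  residual at x̄ is ‖𝓕_F(𝓕_M(x̄)+x̄) + 𝓕_M(x̄)‖² (and symmetrically),
  averaged both ways and over the batch. Both networks train jointly each
  step on the shared coordinate batch; each direction also receives its own
  similarity + regularization loss (the regularizer applies to both
  fields), and the cycle term is weighted by α_cyc = 100.
* Fusion: 𝓛_fus = ½[𝓛_sim(F, T_Φ(M)) + 𝓛_sim(F, T_Φ(M′))] replaces the
  raw similarity in the total; the raw term is still logged every epoch.

Totals: standard 𝓛_sim + α_reg·𝓛_reg (α_reg default 0.1); cycle adds
α_cyc·𝓛_cyc; fusion uses 𝓛_fus + α_reg·𝓛_reg.

## Optimization

Per step one random 32³ patch (16³ at desk scale) is drawn uniformly with
replacement; the field is evaluated at the patch's voxel coordinates, the
moving image is sampled at Φ(x̄) by differentiable trilinear interpolation
(border replication outside the volume), and one AdamW step (lr 10⁻⁴,
weight decay at the conventional 0.01 — only the optimizer and learning
rate are prescribed) is taken on the patch loss. An epoch is a fixed
number of patches (500 at full scale) regardless of image size; no early
stopping. Batch size is one patch per step; intensities are min-max
normalized to [0, 1] before training (NCC is affine-invariant, but a fixed
range keeps interpolation diagnostics and fusion mixing comparable).
All randomness flows from explicit seeds: fixed seeds give bit-identical
initializations, patch sequences and training trajectories.

The cascade trains stage 1 to completion, freezes it, and trains a second
network on Φ_C(x̄) = Φ(x̄) + Δx̄′, with the regularizer applied to Φ_C.
The correction network reads the original coordinate x̄ (the additive
form); a `composed` flag feeds it Φ(x̄) instead, for experimentation.
With zero stage-2 epochs no correction exists and the stage-1 result is
returned unchanged. The fusion variant samples all three channels at
Φ(x̄) and mixes them with simplex weights (softmax over 3 logits)
evaluated at the patch coordinates; the weight network is a sine (ω = 30)
network sharing the deformation network's encoding.

## Autodiff core

No GPU autodiff framework is part of the dependency set; the package ships
a small numpy-backed reverse-mode tape (`inrreg._autodiff`) implementing
exactly the operations the model needs (broadcast arithmetic, batched
matmul against 2-D weights, trig/exp/tanh, reductions, concat/reshape,
differentiable trilinear sampling, valid-mode box sums) plus AdamW.
Gradients of every primitive are pinned to central finite differences in
the unit tests. The engine preserves floating dtype end to end: oracle
tests run in float64, while training networks default to float32 at desk
scale (transcendental throughput on one CPU core is several times higher;
at the 10⁻³-scale tolerances of the recovery experiments the precision
difference is immaterial).

## Synthetic data

Phantoms are Voronoi partitions of the full volume (seed points uniform in
the volume, regions labeled 1..K) with distinct per-region mean
intensities in [0.25, 0.95], Gaussian-smoothed by 1.5 voxels, plus smooth
random texture normalized to a standard deviation of 0.03 — about 3% of
the dynamic range, emulating within-tissue MR signal variation. The
texture matters: without it, intensity is locally constant inside regions
and the displacement there is not identifiable from the similarity loss.
Noise (Gaussian, σ = 0.01 by default) is added to the fixed image only,
mimicking inter-subject acquisition noise without altering the moving
image the field acts on. Labels keep the crisp partition; the reserved
background value 0 does not occur in default phantoms.

Analytic fields provide closed-form displacement and Jacobians: identity;
affine (A x̄ + t); a Gaussian bump A·exp(−‖x̄−c‖²/2r²)·û whose amplitude
is capped at 0.95·r·√e so the ground truth is provably diffeomorphic
(the cap can be lifted explicitly to create folding fixtures); and a
low-frequency per-component sinusoid. Each field also has a tape-expressed
form so the autodiff Jacobian can be cross-checked against the closed
form.

What the phantoms do **not** emulate: MRI physics (bias fields, Rician
noise), anatomy-shaped region geometry, and inter-subject appearance
differences beyond additive noise. Passing the synthetic recovery tests
therefore demonstrates correctness of the optimization and the losses, not
clinical-grade registration accuracy.

## Desk-scale protocol

Full-scale settings (176×192×176 volumes, width-256 networks, 40 epochs ×
500 patches of 32³) are the package defaults but constitute a GPU-scale
workload. The reproducible benchmark (`inrreg.protocols`) fixes a
desk-scale study run by `scripts/acceptance.py` and the acceptance tests:
48³ phantoms with 5 regions; the Gaussian-bump pair (r = 0.7, amplitude
0.08, ≈1.9 voxels peak); a 3-layer width-64 float32 network; 16³ patches;
100 patches per epoch; 5 epochs for identity recovery, 8 for bump
recovery and the cycle experiment, and 15 for the ω sweep — folding at
weak regularization (α_reg = 0.01) is a late-training phenomenon, so the
sweep uses the longest budget. These sizes were chosen once as the
benchmark conditions; losses, sampling, optimizer and initialization are
identical to full scale.

## Numerical choices and edge cases

* Warping is pull-back: output voxel x̄ reads the input at Φ(x̄); sample
  indices are computed as voxel index + displacement·(d−1)/2, so a zero
  displacement lands exactly on interpolation nodes and identity warps are
  bit-exact. Out-of-range samples clamp to the border. Labels resample by
  nearest neighbor (no new label values can appear).
* The folding metric differentiates the dense sampled field by central
  finite differences (one-sided at boundaries) rather than autodiff, so it
  applies to any saved field, including fields with no network behind
  them. It is computed over the whole volume, in normalized units — for
  isotropic normalization the determinant sign, hence the folding count,
  is unit-independent.
* Dice is 1 when both masks are empty, 0 when exactly one is; the region
  list excludes background 0.
* Attention's tanh saturates to exactly 1.0 in float64 beyond |arg| ≈ 19,
  so the open-interval bound (10, 50) is exact-arithmetic strict and is
  asserted for realistically scaled pre-activations.
* Non-finite losses abort with the step index and patch corner; non-finite
  field values abort warping with the offending voxel.

## Known limitations

* Per-pair optimization on one CPU core is slow at full scale; the design
  target is correctness and reproducibility, not throughput.
* No inverse-field computation or scaling-and-squaring integration; the
  Jacobian penalty discourages but does not prohibit folding.
* No multi-resolution pyramid; no mutual-information or SSD similarity;
  no bending-energy regularizer.
* The cascade's second stage reads x̄ rather than Φ(x̄) by default; the
  composed alternative is available but untrained by the benchmark.
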