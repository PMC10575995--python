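"""Register a synthetic pair and measure field recovery.

Trains a sine (SIREN) coordinate network from scratch on one moving/fixed
pair at desk scale, then compares the recovered displacement field with the
analytic ground truth: mean endpoint error (EPE), Dice of the warped
labels, and the folding percentage of the recovered field.
"""

import numpy as np

import inrreg as ir
from inrreg.protocols import benchmark_pair, desk_config

bench = benchmark_pair(seed=0)
config = desk_config(omega=30.0, alpha_reg=0.1, epochs=8, seed=0)

result = ir.register(bench["moving"], bench["fixed"], config)

truth_dense = bench["truth"].displacement(
    ir.normalize_grid(bench["moving"].shape).points
)
epe = np.linalg.norm(result.field.reshape(-1, 3) - truth_dense, axis=1).mean()
warped = ir.warp_labels(bench["moving_labels"], result.field)
dice_avg, dice_min, _ = ir.dice_summary(warped, bench["fixed_labels"])

print(f"trained {config.epochs} epochs x {config.patches_per_epoch} patches "
      f"in {result.seconds:.0f}s")
print(f"final similarity loss: {result.history[-1].similarity:.4f} "
      "(0 = perfect local+global correlation)")
print(f"mean endpoint error: {epe:.4f} normalized units = "
      f"{100 * epe / bench['mean_true_magnitude']:.1f}% of the true mean magnitude")
print(f"Dice after registration: avg {dice_avg:.3f}, worst region {dice_min:.3f}")
print(f"folding: {result.folding_pct():.3f}% non-positive Jacobian determinants")
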