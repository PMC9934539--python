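"""Deconvolve a continuous differentiation process.

Simulates a bifurcating differentiation trajectory, samples a pseudo-bulk with
a Gaussian kernel on pseudotime (mimicking an asynchronous population), and
checks that the inferred per-cell probabilities recover the kernel: both as a
per-cell correlation and as the probability-weighted expected pseudotime,
which should land near the kernel center.
"""

import numpy as np

from rankdecon import (RunConfig, SimConfig, expected_value, infer_abundance,
                       make_bulk_kernel, simulate_trajectory, train_model)

sc = simulate_trajectory(SimConfig(
    n_genes=1000, n_cells=600, group_probs=(1 / 3, 1 / 3, 1 / 3),
    de_prob=0.05, de_fac_loc=0.8, topology=(0, 1, 1), n_steps=10, seed=4))
print(f"trajectory reference: {sc.n_cells} cells on 3 branches, "
      f"pseudotime {sc.pseudotime.min():.0f}..{sc.pseudotime.max():.0f}")

model = train_model(sc.counts, config=RunConfig(
    n_var_genes=400, n_dims=8, n_train=800, seed=5))

bulk = make_bulk_kernel(sc, n_draws=1000, capture_range=(60, 200), seed=12)
dist = infer_abundance(model, bulk.bulk_counts)

r = np.corrcoef(dist.p.to_numpy(), bulk.truth_cell_probs.to_numpy())[0, 1]
true_mean = float((bulk.truth_cell_probs * sc.pseudotime).sum())
e_iqr = expected_value(dist.p, sc.pseudotime)
e_plain = expected_value(dist.p, sc.pseudotime, iqr_restrict=False)
print(f"\nkernel center = {bulk.kernel_center:.1f} (sigma {bulk.kernel_sigma:.2f}), "
      f"true mean pseudotime = {true_mean:.1f}")
print(f"per-cell Pearson r (inferred vs true weights) = {r:.3f}")
print(f"expected pseudotime, IQR-restricted  = {e_iqr:.1f}")
print(f"expected pseudotime, all cells       = {e_plain:.1f}")
print("Both estimates should sit near the true mean pseudotime: the model "
      "localizes the bulk sample along the differentiation axis without any "
      "clustering.  The IQR variant trims extreme probabilities, which "
      "stabilizes the estimate on noisy real data but can bias it when the "
      "distribution peaks at a trajectory boundary.")
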