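"""Choose the component count k by twofold cross-validation.

The out-of-sample reconstruction error falls steeply while k is below the
true component count and flattens beyond it; the elbow rule picks the point
where adding components stops paying off.
"""

import numpy as np

import sccdyn as sd

truth = sd.make_ground_truth(
    n_rois=16, n_networks=4, k_star=3, sparsity=0.2,
    n_subjects=10, w=30, target_snr=15.0, seed=2,
)
stacks = sd.synth_windowed_stack(truth)

grid = sd.grid_search(stacks, k_values=[1, 2, 3, 4, 5, 6],
                      lambda_values=[0.02], seed=2)
for k, err in zip(grid.k_values, grid.test_error[:, 0]):
    marker = "  <- chosen" if k == grid.chosen_k else ""
    print(f"k={k}: cv error {err:.4f}{marker}")
# the error stops improving once k reaches the planted component count (3)
print(f"operating point: k={grid.chosen_k}, lambda={grid.chosen_lambda}")
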