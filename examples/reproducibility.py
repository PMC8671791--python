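"""Stability of the learned components across cohort subsamples.

Splits the cohort into three subsamples, re-learns the components in each,
and matches them back to the full-sample reference by eta-squared. High
matched similarity means the components are a property of the population,
not of a particular subject split.
"""

import numpy as np

import sccdyn as sd

truth = sd.make_ground_truth(
    n_rois=16, n_networks=4, k_star=3, sparsity=0.2,
    n_subjects=15, w=30, target_snr=15.0, seed=6,
)
stacks = sd.synth_windowed_stack(truth)

reports = sd.reproducibility_sweep(stacks, k=3, lambda_=0.05, seed=6,
                                   subsample_groups=3)
for name, rep in reports.items():
    print(f"{name}: matched eta^2 = {np.round(rep.matched_eta2, 3)} "
          f"(mean {rep.summary_mean:.3f} +/- {rep.summary_sd:.3f})")
# each subsample recovers essentially the same components as the full cohort
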