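"""Discriminate two groups from the temporal expression of components.

Half the cohort carries a planted increase in the temporal variance of one
component's time course (the spatial components themselves are identical
across groups). Leave-one-out linear SVM on the 2k temporal features (per-
component mean intensity and temporal variance) separates the groups.
"""

import sccdyn as sd

truth = sd.make_ground_truth(
    n_rois=16, n_networks=4, k_star=3, sparsity=0.2,
    n_subjects=16, w=40, target_snr=10.0,
    effect_spec=[sd.EffectSpec(component=1, sd_scale=1.6)], seed=3,
)
stacks = sd.synth_windowed_stack(truth)

res = sd.loocv_classify(stacks, truth.labels, k=3, lambda_=0.05, seed=3)
print(f"LOOCV accuracy:    {100 * res.accuracy:.1f}%")
print(f"sensitivity:       {100 * res.sensitivity:.1f}%  (patient recall)")
print(f"specificity:       {100 * res.specificity:.1f}%  (control recall)")
# accuracy well above 50% shows the group difference lives in the temporal
# expression of the shared components, not in their spatial patterns
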