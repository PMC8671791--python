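# sccdyn

Sparse dictionary learning of dynamic functional connectivity.

Resting-state fMRI connectivity is not static: correlations between brain
regions drift over the course of a scan. `sccdyn` decomposes these dynamics
into a small set of **sparse connectivity components (SCCs)** — group-shared
sparse patterns over region pairs — together with subject-specific time
courses that say how strongly each component is expressed in each sliding
window. The temporal expression of the components (not their spatial
patterns) then serves as a feature space for single-subject classification,
e.g. separating patients from controls when groups share the same
connectivity architecture but differ in how they traverse it. The package is
aimed at researchers analyzing ROI-level fMRI time series who want a tested,
scriptable implementation of this workflow, including a synthetic
ground-truth generator for validation.

## The model

Each subject's ROI time series is converted to a sliding-window stack
`S(i) ∈ R^{w×p}` of Fisher z-transformed Pearson correlations over the
`p = n(n−1)/2` region pairs (default: 60 s windows, 4 s steps for TR = 2 s).
Subject stacks are row-concatenated into `S ∈ R^{t×p}` and factorized as

    min_{T,C}  ½‖S − TC‖²_F + λ‖C‖₁   s.t.  ‖t_:j‖₂² ≤ 1 for all j,

where the rows of `C ∈ R^{k×p}` are the sparse components and the columns of
`T ∈ R^{t×k}` their window-indexed expression, constrained to the unit ball
to fix the scale. The problem is solved by exact alternating minimization
(LASSO coordinate descent for `C`, ball-projected block coordinate descent
for `T`), so the objective is monotonically non-increasing. Components are
ranked by the norm of their `C` row. Subject-specific loadings `C(i)` re-solve
the LASSO against the subject's block `T(i)` of the group temporal matrix;
held-out subjects get `T(i) = S(i) Cᵀ` by projection.

Around the core factorization the package provides: twofold cross-validated
grid search over `(k, λ)` with an explicit elbow rule; one-sample t-maps with
Benjamini–Hochberg FDR and two-sample group contrasts; η² spatial similarity
with optimal component matching (Hungarian assignment); FFT diagnostics of
the reconstruction; per-component temporal features (mean intensity,
temporal variance) with leave-one-out linear-SVM classification; and
reproducibility sweeps over cohort subsamples and window/step parameters.

## Worked example

`examples/decompose_synthetic.py` plants a 3-component truth in a 12-subject
cohort at SNR 10, learns the decomposition, and matches it back:

```
group stack: 480 windows x 190 edges from 12 subjects
converged in 25 iterations; objective 107.6 -> 16.2
component importance (C row norms): [11.2   5.5   5.35]
matched eta^2 vs planted truth: [1. 1. 1.]
```

Matched η² of 1.0 means every planted spatial pattern was recovered exactly
(up to the factorization's sign/scale conventions); the first component — the
dense within-network baseline — dominates the reconstruction, mirroring its
largest row norm. `examples/select_parameters.py` shows the cross-validation
elbow landing on the planted `k`:

```
k=1: cv error 1.1203
k=2: cv error 0.6409
k=3: cv error 0.1997  <- chosen
k=4: cv error 0.1999
...
operating point: k=3, lambda=0.02
```

and `examples/classify_groups.py` recovers a planted group difference in one
component's temporal variance from the LOOCV temporal features
(`accuracy 93.8%, sensitivity 87.5%, specificity 100.0%` on 16 subjects).
The other examples cover preprocessing + dFC estimation, spectral
diagnostics, and subsample reproducibility. A thin `sccdyn` command-line
interface (`simulate`, `dfc`, `select`, `learn`, `code`, `stats`,
`spectra`, `classify`, `reproducibility`, and `run` for a fully configured
end-to-end pipeline) wraps the same library calls for shell use.

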