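# Methods

## Model and assumptions

The package models a cohort of windowed functional connectomes as sparse
time-varying combinations of shared components. For subject *i*, the stack
`S(i) ∈ R^{w×p}` holds Fisher z-transformed Pearson correlations of every
region pair in `w` sliding windows (`p = n(n−1)/2` pairs for `n` regions).
The group matrix `S = [S(1); …; S(m)] ∈ R^{t×p}` (`t = Σ w_i`) is factorized
as `S ≈ T C` with

- `C ∈ R^{k×p}`: sparse connectivity components (SCCs), one per row, sparse
  over edges via an L1 penalty `λ‖C‖₁`;
- `T ∈ R^{t×k}`: temporal atoms, each column constrained to the unit
  Euclidean ball (`‖t_:j‖₂² ≤ 1`) to remove the scale degeneracy of the
  bilinear model.

The model assumes components are shared across subjects while their
expression is subject-specific, that windowed connectivity is approximately
linear in component expression, and that departures from the low-rank sparse
structure are i.i.d. noise. Subject-level analysis slices the group `T` into
per-subject blocks `T(i)` and re-solves the LASSO for subject-specific
loadings `C(i)`; the reconstruction is `T(i) C(i)`. For subjects not in the
training set (cross-validation, classification folds), `T(i)` is the
projection `S(i) Cᵀ` — the only mechanism available without refitting the
dictionary.

## Optimization

Both half-steps are solved exactly, so the full objective
`½‖S − TC‖² + λ‖C‖₁` is monotone non-increasing (asserted in tests at
tolerance 1e-9 per half-step):

- **Coding step.** Cyclic coordinate descent on the Gram system
  (`G = TᵀT`, `B = TᵀS`): the update for coordinate *a* across all `p`
  target columns simultaneously is a soft-threshold,
  `c_a ← soft(b_a − Σ_{j≠a} G_{aj} c_j, λ)/G_{aa}`. Convergence when the
  largest coordinate change falls below 1e-10 × scale (at most 1000 sweeps);
  at that point the KKT residual is below 1e-6 on test problems. Atoms with
  numerically zero norm (≤ 1e-12) get zero coefficients.
- **Dictionary step.** Block coordinate descent over columns of `T`; each
  column's unconstrained least-squares minimizer is projected onto the unit
  ball, which solves that column's constrained subproblem exactly. Columns
  whose `C` row is entirely zero ("dead atoms") are left untouched and
  re-seeded afterwards from the residual's leading left-singular direction
  (10 power iterations); because their loading row is zero this cannot
  change the objective.
- **Initialization.** Atoms drawn from a seeded standard normal and
  projected onto the unit ball (`init="normal"`, default); seeding from
  noisy data columns is available as `init="data"`.
- **Convergence.** Relative objective decrease below `tol = 1e-5` or
  `max_iter = 200` outer iterations (non-convergence returns the best
  iterate with a warning).
- **Canonical form.** Components are ranked by descending `C` row norm
  (stable sort; ties keep fit order) and sign-flipped so each row's sum is
  non-negative; both operations leave `T C` unchanged.

## Parameters that matter

| parameter | meaning | default | rationale |
|---|---|---|---|
| `window_trs` / `step_trs` | sliding-window length / step, in TRs | 30 / 2 | 60 s windows, 4 s steps at TR = 2 s — the conventional balance between temporal resolution and correlation estimate quality |
| `k` | number of components | chosen by CV (grid search) | the elbow of the twofold CV error; 10 is a typical operating point at full scale |
| `λ` | sparsity of loadings | chosen by CV | smallest value whose best error is within the elbow threshold of the global minimum |
| `clip` | Fisher clipping | 1e-7 | keeps `atanh` finite at r = ±1 |
| `improvement_threshold` | elbow rule | 0.02 | a 2 % relative improvement is treated as "no longer significant" |
| `q` / `alpha` | FDR level / test level | 0.05 | standard |
| `svm_c` | SVM regularization | 1.0 | fixed, no inner tuning loop (switchable) |

Band-pass filtering is a zero-phase forward–backward Butterworth (order 4
per pass) at 0.01–0.08 Hz; no particular filter family is canonical for this
band, and the zero-phase property avoids shifting connectivity dynamics.
Confound regression residualizes on an intercept, the supplied regressors,
and optionally their backward differences ("first-order derivatives", first
row zero); collinear columns are dropped with a warning. Whether filtering
precedes regression is the caller's choice; the CLI applies filtering first.

## Cross-validated model selection

Subjects are split into two random folds (seeded). For each `(k, λ)`,
components are learned on one fold; each test subject's temporal matrix is
the raw projection `S C_trainᵀ` (no pseudo-inverse — the subsequent LASSO
refit of `C_test(i)` absorbs any scale), and the error is

    Σ_i ‖S_test(i) − T_test(i) C_test(i)‖² / Σ_i ‖S_test(i) − S̄_test‖²,

with `S̄_test` the element-wise mean of the test stacks (window-wise grand
mean if window counts differ across subjects). Both fold directions are
evaluated and averaged, using all data symmetrically. The ratio is exactly 0
for perfect reconstruction and exactly 1 for reconstruction at the test
average. The elbow rule is made explicit rather than visual: the chosen `k`
is the largest grid value whose error improves on its predecessor by more
than the threshold (smallest grid point if none does), and the chosen `λ` is
the smallest whose column minimum is within the threshold of the global
minimum; threshold 0 degenerates to the global minimizer.

## Similarity, matching and group statistics

η² between two edge-vectors is
`1 − Σ[(a_i−m_i)² + (b_i−m_i)²] / Σ[(a_i−M̄)² + (b_i−M̄)²]` with `m_i` the
positionwise mean and `M̄` the grand mean: 1 for identity, 0 for `b = −a`,
and sensitive to level shifts (η²(a, a+c) < 1), unlike correlation.

Because the unit-ball constraint pushes the factorization's scale into `C`,
raw loading magnitudes are not comparable across fits. Component matching
therefore normalizes rows to unit norm, scores each pair at its better sign
orientation (`max(η²(a,b), η²(a,−b))`), and finds the assignment maximizing
total similarity — exhaustively for `k ≤ 6`, by the Hungarian algorithm
above that (both optimal; cross-checked in tests).

Group-level maps are edgewise one-sample t-tests of the subject-specific
loadings against zero, Benjamini–Hochberg corrected **within each
component** across its `p` edges (correcting across all `k×p` tests at once
is available via `fdr_scope="pooled"`); non-survivors and zero-variance
edges are zeroed. Between-group contrasts are pooled-variance two-sample
t-tests, reported uncorrected at α = 0.05 by default (FDR switchable), with
an optional |t| display threshold for plotting conventions.

## Spectral diagnostics

Connectivity series are sampled once per window step, demeaned per edge,
and transformed with a one-sided FFT; the report carries the median power
across edges per frequency bin for the original, reconstructed, and residual
series. The reference cutoff is 1/window-length Hz — the sliding window's
effective low-pass corner on connectivity dynamics — and the diagnostic
claim, asserted on synthetic fixtures, is that the reconstruction's power
above that cutoff is strictly below the original's (the denoising effect of
the low-rank sparse reconstruction).

## Classification

Features are the per-component mean intensity (signed mean) and temporal
variance (unbiased, `w−1` denominator) of the subject's temporal matrix, in
ranked component order — `2k` values per subject. Leave-one-out folds are
fully self-contained: components are re-learned from the training subjects
only; training features come from the row blocks of the fold's `T`;
the held-out subject's temporal matrix is projected against the fold's
loadings **after rescaling the decomposition so `C` rows have unit norm**
(scale moves into `T`), which puts the projection `S Cᵀ` on the same scale
as the sliced training blocks — without this convention the two feature
sources are incommensurate. Features are z-scored with training-fold
statistics only (constant columns map to 0); a linear SVM with fixed C = 1
predicts the held-out label. Per-fold ranking by row norm makes feature
positions comparable across folds without cross-fold component matching.
Accuracy/sensitivity/specificity satisfy the usual confusion-matrix
identities exactly; the null-generator check (chance-level accuracy on
cohorts with no planted effect) guards against leakage.

## Synthetic ground truth

The generator emulates the structure the model assumes, not raw BOLD
physics:

- **Spatial.** Component 1 is a dense positive within-network baseline
  (uniform 0.4–0.8 weights inside each of the `n_networks` equal blocks);
  each further component draws exactly `round(sparsity·p)` nonzeros from the
  union of two between-network blocks, positive in one and negative in the
  other (anticorrelated block pairs). Infeasible sparsity for the block
  sizes raises an error.
- **Temporal.** Atoms are moving-average-smoothed (length 5 windows)
  Gaussian series with per-component mean and spread (baseline: mean 0.12,
  sd 0.02; others: 0.04 / 0.06, stated at 50 windows), scaled by
  `sqrt(50/w)` so the unit-ball norm is independent of `w` and planted
  effects are never clipped by projection. Group-1 subjects optionally get a
  mean shift and/or an sd scale on designated components (an sd scale of
  1.5 plants a variance ratio of 2.25).
- **Noise.** White Gaussian on the stack; `noise_sd` defaults to the value
  realizing a requested signal-to-noise power ratio (default SNR 10) on the
  generated signal.
- **Two routes.** Stacks are generated directly in window space by default
  (isolates factorization behavior from dFC estimation error); ROI-level
  series are piecewise-stationary multivariate Gaussians whose segment
  correlation targets devectorize scaled combinations of the planted
  loadings (`tanh` squashing, then the smallest convex shrinkage toward the
  identity that is positive definite, by bisection at tolerance 1e-6).

What passing tests on this generator do *not* show: robustness to
hemodynamic confounds, scanner drift and motion artifacts, non-Gaussian or
temporally autocorrelated noise, imperfectly block-structured components, or
subject-varying spatial patterns. Results on real data depend on those
factors; the synthetic results validate the algorithms, not the biology.

## Recovery metric

"Relative reconstruction error" on planted data is measured against the
noiseless planted signal, `‖T̂Ĉ − T*C*‖_F / ‖T*C*‖_F` — the quantity that can
actually approach zero; the residual against the noisy stack is bounded
below by the noise floor (≈ `1/√(1+SNR)` relative) regardless of recovery
quality.

## Problem sizes

Study-scale validation runs use 30-subject cohorts with 60 nodes
(p = 1770 edges), 50 windows and SNR 10 for recovery and model selection,
and 30 subjects with 30 nodes (p = 435) for the leave-one-out
classification experiments — sizes chosen as desk-scale analogues of a
typical two-group resting-state cohort while keeping a full validation run
in the minutes range on one CPU.

## Known limitations

- The factorization is non-convex; different seeds can reach different
  local minima. Ranking + sign canonicalization remove the label/sign
  ambiguity but not local-minimum variability (the reproducibility sweep
  quantifies it).
- The projection `S Cᵀ` for held-out subjects is exact only for orthonormal
  loading rows; for correlated components it biases temporal estimates
  (mitigated, not removed, by the unit-norm row convention).
- Equal window counts per subject are assumed by the element-wise test
  average in cross-validation; unequal counts fall back to a grand-mean row.
- FDR within component treats each component's edge map as the family of
  tests; pooling across components is stricter and switchable.
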