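"""Cross-validated selection of the component count k and sparsity lambda.

The free parameters of the factorization trade goodness of fit against
parsimony: test error falls as k grows or lambda shrinks, but flattens once
the genuine structure is captured. A twofold cross-validation estimates
out-of-sample reconstruction error: components are learned on one half of the
subjects, each held-out subject's temporal matrix is obtained by projecting
its stack onto the learned loadings (``T = S C'``), its sparse components are
re-coded by LASSO against that temporal matrix, and the summed squared
reconstruction error is normalized by the spread of the test stacks around
their subject-average. Both fold directions are evaluated and averaged. The
operating point is the smallest (k, lambda) past which the error stops
improving appreciably (an explicit elbow rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dfc import GroupStack, WindowedConnectome, concatenate_subjects
from .decomposition import code_subject, learn_group_sccs

__all__ = [
    "GridResult",
    "project_temporal",
    "cv_test_error",
    "grid_search",
    "pick_operating_point",
]


def project_temporal(
    s_test: WindowedConnectome | np.ndarray, c_train: np.ndarray
) -> np.ndarray:
    """Held-out subject's temporal matrix: the plain product S x C' (w x k)."""
    S = s_test.data if isinstance(s_test, WindowedConnectome) else np.asarray(s_test)
    C = np.asarray(c_train, dtype=float)
    if S.ndim != 2:
        raise ValueError("test stack must be 2-D")
    if S.shape[1] != C.shape[1]:
        raise ValueError(
            f"edge count mismatch: stack has {S.shape[1]}, loadings have "
            f"{C.shape[1]}"
        )
    return S @ C.T


def _test_mean(stacks: list[np.ndarray]) -> np.ndarray:
    """Subject-average stack; window-wise grand mean when widths differ."""
    widths = {s.shape[0] for s in stacks}
    if len(widths) == 1:
        return np.mean(stacks, axis=0)
    grand = np.vstack(stacks).mean(axis=0)  # 1 x p row, broadcast later
    return grand[None, :]


def cv_test_error(
    test_subjects: list[WindowedConnectome],
    c_train: np.ndarray,
    lambda_: float,
    reconstructions: list[np.ndarray] | None = None,
) -> float:
    """Relative out-of-sample reconstruction error over the test subjects.

    sum_i ||S_i - T_i C_i||^2 / sum_i ||S_i - S_bar||^2 with S_bar the
    element-wise mean of the test subjects' stacks. ``reconstructions``
    overrides the model path (used in tests of the ratio's boundary cases).
    """
    if len(test_subjects) < 2:
        raise ValueError("need at least 2 test subjects")
    stacks = [np.asarray(s.data, float) for s in test_subjects]
    sbar = _test_mean(stacks)
    denom = sum(float(np.sum((s - sbar) ** 2)) for s in stacks)
    if denom <= 0:
        raise ValueError(
            "zero test variance: all test stacks are identical, the relative "
            "error is undefined"
        )
    num = 0.0
    for i, s in enumerate(test_subjects):
        if reconstructions is not None:
            rec = reconstructions[i]
        else:
            t_i = project_temporal(s, c_train)
            dec = code_subject(s, t_i, lambda_)
            rec = dec.T_i @ dec.C_i
        num += float(np.sum((stacks[i] - rec) ** 2))
    return num / denom


@dataclass
class GridResult:
    """Twofold-CV error surface over the (k, lambda) grid."""

    k_values: list[int]
    lambda_values: list[float]
    test_error: np.ndarray  # |k| x |lambda|
    chosen_k: int
    chosen_lambda: float
    fold_assignment: dict[str, int] = field(default_factory=dict)
    seed: int = 0


def grid_search(
    subjects: list[WindowedConnectome],
    k_values: list[int],
    lambda_values: list[float],
    seed: int = 0,
    improvement_threshold: float = 0.02,
    max_iter: int = 200,
    tol: float = 1e-5,
) -> GridResult:
    """Twofold cross-validated error for every (k, lambda) pair.

    Subjects are split into two seeded random folds; for each grid cell the
    components are learned on one fold and scored on the other, in both
    directions, and the two errors averaged.
    """
    if len(subjects) < 4:
        raise ValueError("grid search needs at least 4 subjects")
    k_values = sorted(int(k) for k in k_values)
    lambda_values = sorted(float(v) for v in lambda_values)
    if not k_values or not lambda_values:
        raise ValueError("empty parameter grid")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(subjects))
    half = len(subjects) // 2
    folds = [perm[:half].tolist(), perm[half:].tolist()]
    assignment = {
        subjects[i].subject_id or str(i): f
        for f, idx in enumerate(folds)
        for i in idx
    }

    errors = np.zeros((len(k_values), len(lambda_values)))
    for a, ki in enumerate(k_values):
        for b, lam in enumerate(lambda_values):
            vals = []
            for train_idx, test_idx in (folds, folds[::-1]):
                train = concatenate_subjects([subjects[i] for i in train_idx])
                dec = learn_group_sccs(
                    train, k=ki, lambda_=lam, seed=seed,
                    max_iter=max_iter, tol=tol,
                )
                vals.append(
                    cv_test_error(
                        [subjects[i] for i in test_idx], dec.C, lam
                    )
                )
            errors[a, b] = float(np.mean(vals))

    grid = GridResult(
        k_values=k_values,
        lambda_values=lambda_values,
        test_error=errors,
        chosen_k=k_values[0],
        chosen_lambda=lambda_values[0],
        fold_assignment=assignment,
        seed=seed,
    )
    grid.chosen_k, grid.chosen_lambda = pick_operating_point(
        grid, improvement_threshold
    )
    return grid


def pick_operating_point(
    grid: GridResult, improvement_threshold: float = 0.02
) -> tuple[int, float]:
    """Elbow rule: stop where extra components/sparsity stop paying off.

    lambda: the smallest grid value whose best-over-k error is within
    ``improvement_threshold`` (relative) of the global minimum. k: at that
    lambda, the largest k whose error improves on the previous grid k by more
    than the threshold (relative); the smallest grid k when none does. With
    threshold 0 this degenerates to the global minimizer.
    """
    E = np.asarray(grid.test_error, dtype=float)
    if not np.all(np.isfinite(E)):
        raise ValueError("error surface contains non-finite values")
    col_min = E.min(axis=0)
    gmin = E.min()
    ok = col_min <= (1.0 + improvement_threshold) * gmin
    b = int(np.flatnonzero(ok)[0])
    lam = grid.lambda_values[b]

    col = E[:, b]
    chosen = 0
    for a in range(1, len(grid.k_values)):
        rel_gain = (col[a - 1] - col[a]) / max(col[a - 1], np.finfo(float).tiny)
        if rel_gain > improvement_threshold:
            chosen = a
    return grid.k_values[chosen], lam
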