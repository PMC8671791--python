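"""Sparse dictionary learning of windowed connectivity stacks.

The group stack ``S (t x p)`` is factorized as ``S = T x C`` where the columns
of ``T`` are window-indexed expression time courses (temporal atoms) confined
to the unit Euclidean ball, and the rows of ``C`` are sparse connectivity
components (SCCs) over edge pairs. The fit minimizes

    1/2 ||S - T C||_F^2 + lambda ||C||_1,   s.t. ||t_:j||_2^2 <= 1 for all j,

by alternating exact minimization: an L1-regularized LASSO update of ``C``
with ``T`` fixed (coordinate descent on the Gram system, vectorized across
edge columns) and block coordinate descent over the columns of ``T`` with
``C`` fixed, each column closed by projection onto the unit ball. Both
half-steps solve their subproblem exactly, so the objective is monotonically
non-increasing.

Subject-specific decompositions reuse the group atoms: a subject's temporal
matrix ``T(i)`` is the corresponding row block of the group ``T``, and the
subject's sparse components ``C(i)`` re-solve the LASSO against that block.
Components are ranked by the Euclidean norm of their ``C`` row (importance
for the reconstruction) and sign-canonicalized so the loading sum of each
component is non-negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dfc import GroupStack, WindowedConnectome

__all__ = [
    "GroupDecomposition",
    "SubjectDecomposition",
    "lasso_code",
    "dictionary_update",
    "learn_group_sccs",
    "code_subject",
    "reconstruct",
    "rank_components",
    "canonicalize_signs",
    "factor_objective",
    "unit_row_form",
]

_DEAD_ATOM_EPS = 1e-12


def factor_objective(
    S: np.ndarray, T: np.ndarray, C: np.ndarray, lambda_: float
) -> float:
    """1/2 ||S - TC||_F^2 + lambda ||C||_1."""
    resid = S - T @ C
    return 0.5 * float(np.sum(resid * resid)) + lambda_ * float(
        np.sum(np.abs(C))
    )


def lasso_code(
    targets: np.ndarray,
    dictionary: np.ndarray,
    lambda_: float,
    max_iter: int = 1000,
    tol: float = 1e-10,
) -> np.ndarray:
    """Solve min_C 1/2 ||S - D C||_F^2 + lambda ||C||_1 column by column.

    Cyclic coordinate descent on the Gram system (G = D'D, B = D'S), updating
    one dictionary coordinate at a time across *all* target columns at once.
    Atoms with (numerically) zero norm receive zero coefficients.
    """
    if lambda_ < 0:
        raise ValueError("lambda_ must be non-negative")
    D = np.asarray(dictionary, dtype=float)
    S = np.asarray(targets, dtype=float)
    if not np.all(np.isfinite(D)):
        raise ValueError("dictionary contains non-finite values")
    if S.ndim == 1:
        S = S[:, None]
    if D.shape[0] != S.shape[0]:
        raise ValueError("dictionary and targets disagree on row count")
    k = D.shape[1]
    G = D.T @ D
    B = D.T @ S
    diag = np.diag(G).copy()
    alive = diag > _DEAD_ATOM_EPS
    C = np.zeros((k, S.shape[1]))
    scale = max(1.0, np.abs(B).max(initial=0.0))
    for _ in range(max_iter):
        delta = 0.0
        for a in range(k):
            if not alive[a]:
                continue
            rho = B[a] - G[a] @ C + diag[a] * C[a]
            new = np.sign(rho) * np.maximum(np.abs(rho) - lambda_, 0.0) / diag[a]
            step = np.abs(new - C[a]).max(initial=0.0)
            if step > delta:
                delta = step
            C[a] = new
        if delta <= tol * scale:
            break
    return C


def dictionary_update(
    S: np.ndarray,
    C: np.ndarray,
    T_prev: np.ndarray,
    n_passes: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Minimize 1/2 ||S - TC||_F^2 over T with unit-ball columns.

    Block coordinate descent over columns of ``T``; each column's exact
    unconstrained minimizer is projected onto the unit Euclidean ball, which
    is the constrained optimum for that block. Returns the updated ``T`` and
    a boolean mask of dead atoms (all-zero ``C`` rows), whose columns are
    left untouched and should be re-initialized by the caller.
    """
    T = np.array(T_prev, dtype=float, copy=True)
    A = C @ C.T
    B = S @ C.T
    diag = np.diag(A)
    dead = diag <= _DEAD_ATOM_EPS
    for _ in range(n_passes):
        for j in range(T.shape[1]):
            if dead[j]:
                continue
            u = T[:, j] + (B[:, j] - T @ A[:, j]) / diag[j]
            nrm = np.linalg.norm(u)
            if nrm > 1.0:
                u /= nrm
            T[:, j] = u
    return T, dead


@dataclass
class GroupDecomposition:
    """Fitted group factorization S ~ T x C with bookkeeping."""

    T: np.ndarray
    C: np.ndarray
    k: int
    lambda_: float
    seed: int
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = True

    @property
    def row_norms(self) -> np.ndarray:
        return np.linalg.norm(self.C, axis=1)

    def subject_temporal(self, stack: GroupStack, i: int) -> np.ndarray:
        """The subject's row block of the group temporal matrix, w x k."""
        return self.T[stack.subject_slice(i)]


@dataclass
class SubjectDecomposition:
    """Subject-level refit: temporal matrix T_i and sparse components C_i."""

    T_i: np.ndarray
    C_i: np.ndarray
    subject_id: str = ""
    lambda_: float = 0.0


def rank_components(dec: GroupDecomposition) -> GroupDecomposition:
    """Sort components by descending C-row norm (stable; ties keep order)."""
    order = np.argsort(-dec.row_norms, kind="stable")
    dec.C = dec.C[order]
    dec.T = dec.T[:, order]
    return dec


def canonicalize_signs(dec: GroupDecomposition) -> GroupDecomposition:
    """Flip components whose loading sum is negative; T x C is unchanged."""
    sums = dec.C.sum(axis=1)
    flip = sums < 0
    dec.C[flip] *= -1
    dec.T[:, flip] *= -1
    return dec


def _reinit_dead_atoms(
    T: np.ndarray, C: np.ndarray, S: np.ndarray, dead: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Re-seed dead atoms from the residual's leading left-singular direction.

    The dead component's C row is zero, so replacing its T column leaves the
    objective unchanged while giving the next coding step a useful direction.
    """
    if not dead.any():
        return
    R = S - T @ C
    u = rng.standard_normal(R.shape[0])
    u /= np.linalg.norm(u)
    for _ in range(10):  # power iteration on R R'
        u = R @ (R.T @ u)
        nrm = np.linalg.norm(u)
        if nrm <= _DEAD_ATOM_EPS:  # residual numerically zero
            break
        u /= nrm
    first = True
    for j in np.flatnonzero(dead):
        if first:
            T[:, j] = u
            first = False
        else:  # further dead atoms: random unit directions
            v = rng.standard_normal(R.shape[0])
            T[:, j] = v / np.linalg.norm(v)


def learn_group_sccs(
    stack: GroupStack | np.ndarray,
    k: int,
    lambda_: float,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-5,
    init: str = "normal",
) -> GroupDecomposition:
    """Fit k sparse connectivity components to a group stack.

    Alternates LASSO coding of ``C`` and ball-constrained updates of ``T``
    from a seeded random initialization until the relative objective change
    drops below ``tol`` or ``max_iter`` is reached. The returned decomposition
    is ranked by component importance and sign-canonicalized; the recorded
    objective trace (one entry per half-step) is non-increasing.

    ``init='normal'`` draws atoms from a standard normal projected onto the
    unit ball; ``init='data'`` seeds atoms from random rows of ``S``
    transposed into window space — kept as an alternative, rarely needed.
    """
    S = stack.data if isinstance(stack, GroupStack) else np.asarray(stack, float)
    t, p = S.shape
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > min(t, p):
        raise ValueError(f"k={k} exceeds min(t, p) = {min(t, p)}")
    rng = np.random.default_rng(seed)

    if init == "normal":
        T = rng.standard_normal((t, k))
    elif init == "data":
        # random sparse combinations of data columns as initial time courses
        cols = rng.integers(0, p, size=k)
        T = S[:, cols] + 1e-3 * rng.standard_normal((t, k))
    else:
        raise ValueError(f"unknown init {init!r}")
    norms = np.linalg.norm(T, axis=0)
    T /= np.maximum(norms, 1.0)

    trace: list[float] = []
    C = np.zeros((k, p))
    prev = np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        C = lasso_code(S, T, lambda_)
        trace.append(factor_objective(S, T, C, lambda_))
        T, dead = dictionary_update(S, C, T)
        _reinit_dead_atoms(T, C, S, dead, rng)
        obj = factor_objective(S, T, C, lambda_)
        trace.append(obj)
        if np.isfinite(prev) and prev - obj <= tol * max(abs(prev), 1.0):
            converged = True
            break
        prev = obj
    if not converged:
        warnings.warn(
            f"dictionary learning did not converge in {max_iter} iterations; "
            "returning the best iterate",
            stacklevel=2,
        )
    dec = GroupDecomposition(
        T=T,
        C=C,
        k=k,
        lambda_=lambda_,
        seed=seed,
        objective_trace=trace,
        n_iter=n_iter,
        converged=converged,
    )
    return canonicalize_signs(rank_components(dec))


def code_subject(
    s_i: WindowedConnectome | np.ndarray,
    t_i: np.ndarray,
    lambda_: float,
    subject_id: str = "",
) -> SubjectDecomposition:
    """Subject-specific sparse components given a fixed temporal matrix."""
    data = s_i.data if isinstance(s_i, WindowedConnectome) else np.asarray(s_i)
    if isinstance(s_i, WindowedConnectome):
        subject_id = subject_id or s_i.subject_id
    if t_i.shape[0] != data.shape[0]:
        raise ValueError(
            f"temporal matrix has {t_i.shape[0]} windows, data has "
            f"{data.shape[0]}"
        )
    C_i = lasso_code(data, t_i, lambda_)
    return SubjectDecomposition(
        T_i=np.asarray(t_i, float), C_i=C_i,
        subject_id=subject_id, lambda_=lambda_,
    )


def reconstruct(dec: SubjectDecomposition) -> np.ndarray:
    """Reconstructed windowed connectivity, T_i x C_i (w x p)."""
    return dec.T_i @ dec.C_i


def unit_row_form(dec: GroupDecomposition) -> tuple[np.ndarray, np.ndarray]:
    """Rescale so C rows have unit norm, pushing scale into T.

    Returns ``(T_scaled, C_unit)`` with ``T_scaled @ C_unit == T @ C``. This
    is the convention under which a held-out subject's temporal matrix from
    the projection ``S C_unit'`` lives on the same scale as the row blocks of
    ``T_scaled`` (components with near-orthogonal unit-norm loadings make the
    projection an approximate identity on the temporal factors). Zero rows
    are left as-is.
    """
    norms = np.linalg.norm(dec.C, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    return dec.T * safe[None, :], dec.C / safe[:, None]
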