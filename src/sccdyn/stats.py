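"""Group statistics, similarity and reproducibility of connectivity components.

Group-level component maps are one-sample t-maps over subjects'
subject-specific loadings, thresholded by Benjamini-Hochberg FDR within each
component; between-group differences use two-sample (pooled-variance) t-tests
per edge or per temporal feature. Spatial similarity between two components
uses the eta-squared index

    eta^2 = 1 - sum_i [(a_i - m_i)^2 + (b_i - m_i)^2]
                / sum_i [(a_i - Mbar)^2 + (b_i - Mbar)^2],

with m_i the positionwise mean of a_i and b_i and Mbar the grand mean of the
two vectors — 1 for identical vectors, 0 for sign-opposite ones, and, unlike
correlation, sensitive to differences in level as well as shape.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as spstats
from scipy.optimize import linear_sum_assignment
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SCCGroupMap",
    "SimilarityReport",
    "group_scc_tmap",
    "edgewise_group_contrast",
    "feature_group_contrast",
    "eta_squared",
    "match_components",
    "pairwise_component_correlation",
    "reproducibility_sweep",
]


@dataclass
class SCCGroupMap:
    """One-sample t-maps per component with FDR survival mask."""

    t_values: np.ndarray  # k x p
    p_values: np.ndarray
    survive_mask: np.ndarray
    q: float = 0.05

    @property
    def thresholded(self) -> np.ndarray:
        return np.where(self.survive_mask, self.t_values, 0.0)


def group_scc_tmap(
    subject_components: list[np.ndarray],
    q: float = 0.05,
    fdr_scope: str = "per_component",
) -> SCCGroupMap:
    """Group-level component maps: edgewise one-sample t vs 0, BH-FDR at q.

    ``fdr_scope='per_component'`` corrects across each component's edges
    separately (default); ``'pooled'`` corrects across all k x p tests at
    once. Edges with zero across-subject variance have no defined t; they are
    zeroed with p = 1 and a warning.
    """
    X = np.stack([np.asarray(c, float) for c in subject_components])  # n,k,p
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects for a group t-map")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} edge(s) with zero across-subject "
            "variance; set to p = 1 and zeroed",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[degenerate] = 0.0
    p = 2.0 * spstats.t.sf(np.abs(t), df=n - 1)
    p[degenerate] = 1.0

    mask = np.zeros_like(p, dtype=bool)
    if fdr_scope == "per_component":
        for a in range(p.shape[0]):
            mask[a] = multipletests(p[a], alpha=q, method="fdr_bh")[0]
    elif fdr_scope == "pooled":
        mask = multipletests(p.ravel(), alpha=q, method="fdr_bh")[0].reshape(
            p.shape
        )
    else:
        raise ValueError(f"unknown fdr_scope {fdr_scope!r}")
    mask &= ~degenerate
    return SCCGroupMap(t_values=t, p_values=p, survive_mask=mask, q=q)


def _two_sample_t(
    A: np.ndarray, B: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled-variance two-sample t and p along axis 0; degenerate -> p=1."""
    nA, nB = A.shape[0], B.shape[0]
    if nA < 2 or nB < 2:
        raise ValueError("need at least 2 subjects per group")
    varA = A.var(axis=0, ddof=1)
    varB = B.var(axis=0, ddof=1)
    pooled = ((nA - 1) * varA + (nB - 1) * varB) / (nA + nB - 2)
    se = np.sqrt(pooled * (1.0 / nA + 1.0 / nB))
    diff = A.mean(axis=0) - B.mean(axis=0)
    degenerate = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    t[degenerate] = 0.0  # undefined; treated as no evidence
    p = 2.0 * spstats.t.sf(np.abs(t), df=nA + nB - 2)
    p[degenerate] = 1.0
    return t, p


@dataclass
class ContrastResult:
    t_values: np.ndarray
    p_values: np.ndarray
    mask: np.ndarray
    alpha: float


def edgewise_group_contrast(
    groupA: list[np.ndarray],
    groupB: list[np.ndarray],
    alpha: float = 0.05,
    fdr: bool = False,
    t_display_threshold: float | None = None,
) -> ContrastResult:
    """Two-sample t per component per edge between two subject groups.

    Uncorrected thresholding at ``alpha`` by default (``fdr=True`` switches to
    BH within each component). ``t_display_threshold`` additionally restricts
    the mask to |t| above a display cut (e.g. 6.0 for headline plots).
    """
    A = np.stack([np.asarray(c, float) for c in groupA])
    B = np.stack([np.asarray(c, float) for c in groupB])
    if A.shape[1:] != B.shape[1:]:
        raise ValueError("groups disagree on component shape")
    t, p = _two_sample_t(A, B)
    if fdr:
        mask = np.zeros_like(p, dtype=bool)
        for a in range(p.shape[0]):
            mask[a] = multipletests(p[a], alpha=alpha, method="fdr_bh")[0]
    else:
        mask = p < alpha
    if t_display_threshold is not None:
        mask &= np.abs(t) > t_display_threshold
    return ContrastResult(t_values=t, p_values=p, mask=mask, alpha=alpha)


def feature_group_contrast(
    featA: np.ndarray, featB: np.ndarray, alpha: float = 0.05
) -> ContrastResult:
    """Two-sample t per temporal feature (2k columns) between groups."""
    A = np.atleast_2d(np.asarray(featA, float))
    B = np.atleast_2d(np.asarray(featB, float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("feature tables disagree on column count")
    t, p = _two_sample_t(A, B)
    return ContrastResult(
        t_values=t, p_values=p, mask=p < alpha, alpha=alpha
    )


def eta_squared(a: np.ndarray, b: np.ndarray) -> float:
    """Eta-squared similarity of two equal-length vectors (at most 1)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    m = 0.5 * (a + b)
    grand = 0.5 * (a.mean() + b.mean())
    num = np.sum((a - m) ** 2 + (b - m) ** 2)
    den = np.sum((a - grand) ** 2 + (b - grand) ** 2)
    if den == 0:
        raise ValueError(
            "eta-squared undefined: both vectors are the same constant"
        )
    return 1.0 - float(num / den)


@dataclass
class SimilarityReport:
    """Pairwise eta-squared between two component sets plus best matching."""

    eta2: np.ndarray  # k_a x k_b
    matching: list[tuple[int, int]]
    matched_eta2: np.ndarray
    summary_mean: float = 0.0
    summary_sd: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.matched_eta2.size:
            self.summary_mean = float(np.mean(self.matched_eta2))
            self.summary_sd = float(np.std(self.matched_eta2, ddof=1)) if (
                self.matched_eta2.size > 1
            ) else 0.0


def _normalized_rows(C: np.ndarray) -> np.ndarray:
    C = np.asarray(C, dtype=float)
    norms = np.linalg.norm(C, axis=1)
    return C / np.where(norms > 0, norms, 1.0)[:, None]


def match_components(
    C_a: np.ndarray, C_b: np.ndarray, label: str = ""
) -> SimilarityReport:
    """Best one-to-one pairing of two component sets by total eta-squared.

    Rows are scaled to unit norm (the factorization's scale lives in the
    temporal factor, so raw loading magnitudes are not comparable across
    fits) and each pair is scored at its better sign orientation,
    max(eta2(a, b), eta2(a, -b)). The assignment maximizing the total score
    is found exhaustively for k <= 6 and by the Hungarian algorithm above
    that; both give the optimal pairing.
    """
    A = _normalized_rows(C_a)
    B = _normalized_rows(C_b)
    if A.shape[1] != B.shape[1]:
        raise ValueError("component sets disagree on edge count")
    ka, kb = A.shape[0], B.shape[0]
    score = np.empty((ka, kb))
    for i in range(ka):
        for j in range(kb):
            score[i, j] = max(
                eta_squared(A[i], B[j]), eta_squared(A[i], -B[j])
            )
    nm = min(ka, kb)
    if max(ka, kb) <= 6:
        best, best_pairs = -np.inf, None
        rows = range(ka)
        for cols in itertools.permutations(range(kb), nm):
            pairs = list(zip(rows, cols))
            tot = sum(score[i, j] for i, j in pairs)
            if tot > best:
                best, best_pairs = tot, pairs
        pairs = best_pairs
    else:
        ri, ci = linear_sum_assignment(-score)
        pairs = list(zip(ri.tolist(), ci.tolist()))[:nm]
    matched = np.array([score[i, j] for i, j in pairs])
    return SimilarityReport(
        eta2=score, matching=pairs, matched_eta2=matched, label=label
    )


def pairwise_component_correlation(C: np.ndarray) -> np.ndarray:
    """Pearson correlation between component loading rows (k x k)."""
    C = np.asarray(C, dtype=float)
    if C.shape[0] < 2:
        raise ValueError("need at least 2 components")
    sd = C.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            "constant component row(s); their correlations are set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(C)
    R[constant, :] = 0.0
    R[:, constant] = 0.0
    np.fill_diagonal(R, 1.0)
    return R


def reproducibility_sweep(
    subjects,
    k: int,
    lambda_: float,
    seed: int = 0,
    subsample_groups: int = 3,
    window_grid_seconds: list[float] | None = None,
    step_grid_trs: list[int] | None = None,
    reference_window_seconds: float | None = None,
    reference_step_trs: int = 1,
    max_iter: int = 200,
    tol: float = 1e-5,
) -> dict[str, SimilarityReport]:
    """Stability of the learned components across subsamples and windowing.

    ``subjects`` may be a list of :class:`~sccdyn.io.ROITimeSeries` (required
    for the window/step sweep, which re-estimates dFC) or of
    :class:`~sccdyn.dfc.WindowedConnectome` (subsample sweep only). Reference
    components are learned on the full sample; each subsample (random split
    into ``subsample_groups`` groups) and each (window, step) combination is
    re-learned and matched back to the reference, reporting matched
    eta-squared mean +/- sd per condition.
    """
    from .dfc import WindowedConnectome, concatenate_subjects, sliding_window_dfc
    from .decomposition import learn_group_sccs
    from .io import ROITimeSeries

    rng = np.random.default_rng(seed)
    reports: dict[str, SimilarityReport] = {}

    is_ts = isinstance(subjects[0], ROITimeSeries)
    if is_ts:
        tr = subjects[0].tr_seconds
        ref_win_s = reference_window_seconds or 30.0 * tr
        ref_win = max(3, int(round(ref_win_s / tr)))
        windowed = [
            sliding_window_dfc(s, ref_win, reference_step_trs)
            for s in subjects
        ]
    else:
        windowed = list(subjects)

    ref = learn_group_sccs(
        concatenate_subjects(windowed), k=k, lambda_=lambda_, seed=seed,
        max_iter=max_iter, tol=tol,
    )

    perm = rng.permutation(len(windowed))
    groups = np.array_split(perm, subsample_groups)
    for g, idx in enumerate(groups):
        if len(idx) < 4:
            raise ValueError(
                f"subsample {g} has {len(idx)} subjects; need at least 4"
            )
        sub = learn_group_sccs(
            concatenate_subjects([windowed[i] for i in idx]),
            k=k, lambda_=lambda_, seed=seed, max_iter=max_iter, tol=tol,
        )
        reports[f"subsample_{g}"] = match_components(
            ref.C, sub.C, label=f"subsample_{g}"
        )

    if window_grid_seconds and is_ts:
        tr = subjects[0].tr_seconds
        for win_s in window_grid_seconds:
            for step in step_grid_trs or [reference_step_trs]:
                win = max(3, int(round(win_s / tr)))
                wc = [sliding_window_dfc(s, win, int(step)) for s in subjects]
                alt = learn_group_sccs(
                    concatenate_subjects(wc), k=k, lambda_=lambda_,
                    seed=seed, max_iter=max_iter, tol=tol,
                )
                key = f"window_{win_s:g}s_step_{int(step)}tr"
                reports[key] = match_components(ref.C, alt.C, label=key)
    elif window_grid_seconds and not is_ts:
        raise ValueError(
            "window/step sweep needs ROI time series, not windowed stacks"
        )
    return reports
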