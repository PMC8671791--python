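"""Sliding-window dynamic functional connectivity (dFC) estimation.

Each subject's ROI time series is converted into a stack of windowed,
Fisher z-transformed Pearson correlation matrices, vectorized over the upper
triangle: ``S(i) in R^{w x p}`` with ``p = n(n-1)/2`` edges. Windows are
rectangular, advance by a fixed step, and are indexed half-open
``[n*step, n*step + window)`` from the first retained volume; no trailing
partial window is formed. The per-subject stacks row-concatenate into the
group matrix ``S in R^{t x p}`` that the decomposition factorizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import ROITimeSeries

__all__ = [
    "WindowedConnectome",
    "GroupStack",
    "edge_index",
    "vectorize_upper",
    "devectorize",
    "sliding_window_dfc",
    "static_connectivity",
    "concatenate_subjects",
]


def edge_index(n_rois: int) -> list[tuple[int, int]]:
    """Lexicographic upper-triangle edge order: 0-based (i, j) pairs, i < j."""
    if n_rois < 2:
        raise ValueError("need at least 2 ROIs")
    iu = np.triu_indices(n_rois, k=1)
    return list(zip(iu[0].tolist(), iu[1].tolist()))


def vectorize_upper(matrix: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Vectorize the strict upper triangle of a symmetric matrix."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("expected a square matrix")
    if np.max(np.abs(m - m.T)) > tol:
        raise ValueError("matrix is not symmetric within tolerance")
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def devectorize(vector: np.ndarray, n_rois: int) -> np.ndarray:
    """Inverse of :func:`vectorize_upper`; diagonal set to zero."""
    v = np.asarray(vector, dtype=float)
    p = n_rois * (n_rois - 1) // 2
    if v.shape != (p,):
        raise ValueError(f"expected vector of length {p}, got {v.shape}")
    out = np.zeros((n_rois, n_rois))
    iu = np.triu_indices(n_rois, k=1)
    out[iu] = v
    out += out.T
    return out


@dataclass
class WindowedConnectome:
    """One subject's windowed connectivity stack (windows x edges, Fisher z)."""

    data: np.ndarray
    n_rois: int
    window_trs: int
    step_trs: int
    tr_seconds: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        p = self.n_rois * (self.n_rois - 1) // 2
        if self.data.ndim != 2 or self.data.shape[1] != p:
            raise ValueError(
                f"data must have p = {p} columns for n_rois = {self.n_rois}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("windowed connectome contains non-finite values")

    @property
    def n_windows(self) -> int:
        return self.data.shape[0]

    @property
    def n_edges(self) -> int:
        return self.data.shape[1]

    @property
    def window_seconds(self) -> float:
        return self.window_trs * self.tr_seconds

    @property
    def step_seconds(self) -> float:
        return self.step_trs * self.tr_seconds


def n_windows(n_timepoints: int, window_trs: int, step_trs: int) -> int:
    """Number of full windows: floor((T - window)/step) + 1."""
    if window_trs > n_timepoints:
        raise ValueError("window longer than the time series")
    return (n_timepoints - window_trs) // step_trs + 1


def sliding_window_dfc(
    ts: ROITimeSeries,
    window_trs: int = 30,
    step_trs: int = 2,
    clip: float = 1e-7,
) -> WindowedConnectome:
    """Windowed Pearson correlation per edge, Fisher z-transformed.

    Correlations are clipped to ``[-1+clip, 1-clip]`` before ``atanh`` so
    perfectly (anti)correlated pairs stay finite. A zero-variance ROI within
    a window yields r = 0 for its edges, with a warning.
    """
    if window_trs < 3:
        raise ValueError("window_trs must be at least 3")
    if window_trs > ts.n_timepoints:
        raise ValueError(
            f"window ({window_trs} TRs) exceeds series length "
            f"({ts.n_timepoints} TRs)"
        )
    w = n_windows(ts.n_timepoints, window_trs, step_trs)
    iu = np.triu_indices(ts.n_rois, k=1)
    out = np.empty((w, iu[0].size))
    warned = False
    for n in range(w):
        seg = ts.data[n * step_trs : n * step_trs + window_trs]
        sd = seg.std(axis=0)
        degenerate = sd == 0
        if degenerate.any() and not warned:
            warnings.warn(
                f"{ts.subject_id or 'subject'}: zero-variance ROI within a "
                "window; its correlations are set to 0",
                stacklevel=2,
            )
            warned = True
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(seg, rowvar=False)
        r[degenerate, :] = 0.0
        r[:, degenerate] = 0.0
        r = np.clip(r[iu], -1 + clip, 1 - clip)
        out[n] = np.arctanh(r)
    return WindowedConnectome(
        data=out,
        n_rois=ts.n_rois,
        window_trs=window_trs,
        step_trs=step_trs,
        tr_seconds=ts.tr_seconds,
        subject_id=ts.subject_id,
    )


def static_connectivity(ts: ROITimeSeries, clip: float = 1e-7) -> np.ndarray:
    """Full-series Fisher-z connectivity (the one-window limit), length p."""
    wc = sliding_window_dfc(
        ts, window_trs=ts.n_timepoints, step_trs=1, clip=clip
    )
    return wc.data[0]


@dataclass
class GroupStack:
    """Row-concatenation of per-subject windowed stacks, t x p."""

    data: np.ndarray
    subject_ids: list[str]
    windows_per_subject: list[int]
    n_rois: int
    window_trs: int
    step_trs: int
    tr_seconds: float
    offsets: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.offsets:
            self.offsets = np.concatenate(
                [[0], np.cumsum(self.windows_per_subject)[:-1]]
            ).tolist()
        if self.data.shape[0] != sum(self.windows_per_subject):
            raise ValueError("row count does not match windows_per_subject")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_edges(self) -> int:
        return self.data.shape[1]

    def subject_slice(self, i: int) -> slice:
        start = self.offsets[i]
        return slice(start, start + self.windows_per_subject[i])

    def subject_block(self, i: int) -> np.ndarray:
        return self.data[self.subject_slice(i)]


def concatenate_subjects(
    connectomes: list[WindowedConnectome],
) -> GroupStack:
    """Stack subjects' windowed connectomes into one group matrix."""
    if not connectomes:
        raise ValueError("no subjects given")
    ref = connectomes[0]
    for wc in connectomes[1:]:
        if wc.n_rois != ref.n_rois:
            raise ValueError("subjects differ in n_rois")
        if (wc.window_trs, wc.step_trs) != (ref.window_trs, ref.step_trs):
            raise ValueError("subjects differ in window/step parameters")
    return GroupStack(
        data=np.vstack([wc.data for wc in connectomes]),
        subject_ids=[wc.subject_id for wc in connectomes],
        windows_per_subject=[wc.n_windows for wc in connectomes],
        n_rois=ref.n_rois,
        window_trs=ref.window_trs,
        step_trs=ref.step_trs,
        tr_seconds=ref.tr_seconds,
    )
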