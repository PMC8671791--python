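"""Synthetic ground truth for every stage of the pipeline.

The generator emulates the statistical structure the factorization assumes:
a group of subjects whose windowed connectivity stacks are time-varying
combinations of a small set of shared sparse components. Component 1 is a
dense within-network "baseline" (strong positive coupling inside each
functional network); the remaining components are sparse between-network
block patterns, built in anticorrelated pairs of network blocks (positive
loadings in one block, negative in the other), mirroring the organization
reported for empirical components. Temporal atoms are smooth (low-pass
moving-average) Gaussian series with a per-component mean and spread, scaled
so each subject's atom stays inside the unit ball. Optional group effects
shift the mean or scale the spread of designated components' atoms for the
patient group, planting a detectable difference in temporal expression while
leaving the spatial components shared.

Two generation routes exist: windowed stacks directly (S_i = T_i C + noise;
the default test path, exercising the factorization without dFC estimation
error), and piecewise-stationary multivariate Gaussian ROI series whose
segment correlation targets are built from the planted components (the
end-to-end path through sliding-window dFC).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .dfc import WindowedConnectome, devectorize, edge_index
from .io import ROITimeSeries

__all__ = [
    "EffectSpec",
    "SyntheticTruth",
    "make_ground_truth",
    "synth_windowed_stack",
    "synth_roi_timeseries",
    "shrink_to_positive_definite",
    "sample_stationary_series",
]


@dataclass
class EffectSpec:
    """Group-1 alteration of one component's temporal atom."""

    component: int
    mean_shift: float = 0.0
    sd_scale: float = 1.0


@dataclass
class SyntheticTruth:
    """Planted decomposition: shared sparse components + per-subject atoms."""

    C_true: np.ndarray  # k* x p
    T_true: list[np.ndarray]  # per subject, w x k*
    labels: np.ndarray  # 0 control / 1 patient
    effect_spec: list[EffectSpec]
    noise_sd: float
    seed: int
    n_rois: int
    n_networks: int
    network_labels: list[str] = field(default_factory=list)
    sparsity: float = 0.1

    @property
    def k_star(self) -> int:
        return self.C_true.shape[0]

    @property
    def n_subjects(self) -> int:
        return len(self.T_true)

    @property
    def w(self) -> int:
        return self.T_true[0].shape[0]

    @property
    def n_edges(self) -> int:
        return self.C_true.shape[1]

    def noiseless_stack(self, i: int) -> np.ndarray:
        return self.T_true[i] @ self.C_true


# atom scale defaults, stated at the reference window count below; actual
# amplitudes scale as sqrt(_W_REF / w) so the unit-ball norm is independent
# of w and group effects are never clipped by the ball projection
_BASE_MEAN, _BASE_SD = 0.12, 0.02
_OTHER_MEAN, _OTHER_SD = 0.04, 0.06
_W_REF = 50
_SMOOTH_LEN = 5  # windows; moving-average length for atom smoothness


def _network_partition(n_rois: int, n_networks: int) -> list[np.ndarray]:
    return np.array_split(np.arange(n_rois), n_networks)


def _block_edges(
    nets: list[np.ndarray], a: int, b: int, pair_to_col: dict
) -> np.ndarray:
    """Edge-vector indices of the (a, b) between-network block."""
    cols = [
        pair_to_col[(min(i, j), max(i, j))]
        for i in nets[a]
        for j in nets[b]
        if i != j
    ]
    return np.unique(cols)


def _smooth_unit_series(w: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth zero-mean series with unit sample standard deviation."""
    x = rng.standard_normal(w + 2 * _SMOOTH_LEN)
    kernel = np.ones(_SMOOTH_LEN) / _SMOOTH_LEN
    x = np.convolve(x, kernel, mode="same")[_SMOOTH_LEN:-_SMOOTH_LEN]
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def make_ground_truth(
    n_rois: int = 60,
    n_networks: int = 6,
    k_star: int = 3,
    sparsity: float = 0.1,
    n_subjects: int = 30,
    w: int = 50,
    effect_spec: list[EffectSpec] | None = None,
    noise_sd: float | None = None,
    target_snr: float = 10.0,
    seed: int = 0,
) -> SyntheticTruth:
    """Build a planted decomposition with network-block sparse components.

    ``sparsity`` is the fraction of nonzero loadings per sparse component
    (component 1, the within-network baseline, is dense within networks and
    exempt). ``noise_sd`` defaults to the value giving the requested signal-
    to-noise power ratio ``target_snr`` on the generated signal. Identical
    seeds reproduce the truth bit-exactly.
    """
    if not (0 < sparsity <= 1):
        raise ValueError("sparsity must be in (0, 1]")
    if k_star < 1:
        raise ValueError("k_star must be at least 1")
    rng = np.random.default_rng(seed)
    edges = edge_index(n_rois)
    p = len(edges)
    pair_to_col = {pair: c for c, pair in enumerate(edges)}
    nets = _network_partition(n_rois, n_networks)
    net_of = np.empty(n_rois, dtype=int)
    for g, idx in enumerate(nets):
        net_of[idx] = g

    C = np.zeros((k_star, p))
    # component 1: dense positive within-network baseline
    for c, (i, j) in enumerate(edges):
        if net_of[i] == net_of[j]:
            C[0, c] = rng.uniform(0.4, 0.8)

    # remaining components: anticorrelated pairs of between-network blocks
    pairs = list(itertools.combinations(range(n_networks), 2))
    rng.shuffle(pairs)
    nnz = max(1, round(sparsity * p))
    pair_iter = itertools.cycle(pairs)
    for row in range(1, k_star):
        pos_block = _block_edges(nets, *next(pair_iter), pair_to_col)
        neg_block = np.setdiff1d(
            _block_edges(nets, *next(pair_iter), pair_to_col), pos_block
        )
        union = np.concatenate([pos_block, neg_block])
        signs = np.concatenate(
            [np.ones(len(pos_block)), -np.ones(len(neg_block))]
        )
        if len(union) < nnz:
            raise ValueError(
                f"sparsity {sparsity} needs {nnz} nonzeros but the network "
                f"blocks of component {row + 1} offer only {len(union)} edges"
            )
        pick = rng.choice(len(union), size=nnz, replace=False)
        C[row, union[pick]] = signs[pick] * rng.uniform(0.4, 0.8, size=nnz)

    labels = np.zeros(n_subjects, dtype=int)
    labels[n_subjects // 2 :] = 1
    effects = list(effect_spec or [])
    for e in effects:
        if not (0 <= e.component < k_star):
            raise ValueError(f"effect targets unknown component {e.component}")

    T_list = []
    for i in range(n_subjects):
        T = np.empty((w, k_star))
        for j in range(k_star):
            mean = _BASE_MEAN if j == 0 else _OTHER_MEAN
            sd = _BASE_SD if j == 0 else _OTHER_SD
            if labels[i] == 1:
                for e in effects:
                    if e.component == j:
                        mean += e.mean_shift
                        sd *= e.sd_scale
            amp = np.sqrt(_W_REF / w)
            T[:, j] = amp * (mean + sd * _smooth_unit_series(w, rng))
            nrm = np.linalg.norm(T[:, j])
            if nrm > 1.0:  # ball projection; rare under the default scales
                T[:, j] /= nrm
        T_list.append(T)

    if noise_sd is None:
        sig_power = float(
            np.mean([np.mean((T @ C) ** 2) for T in T_list])
        )
        noise_sd = float(np.sqrt(sig_power / target_snr))

    network_labels = [f"net{net_of[i] + 1}" for i in range(n_rois)]
    return SyntheticTruth(
        C_true=C,
        T_true=T_list,
        labels=labels,
        effect_spec=effects,
        noise_sd=noise_sd,
        seed=seed,
        n_rois=n_rois,
        n_networks=n_networks,
        network_labels=network_labels,
        sparsity=sparsity,
    )


def synth_windowed_stack(
    truth: SyntheticTruth,
    window_trs: int = 30,
    step_trs: int = 2,
    tr_seconds: float = 2.0,
) -> list[WindowedConnectome]:
    """Windowed stacks S_i = T_i C + Gaussian noise, with nominal metadata.

    The window/step/TR arguments only annotate the stacks (they set the
    nominal sampling of the connectivity series, e.g. for spectra); the data
    are generated directly in window space.
    """
    rng = np.random.default_rng([truth.seed, 7])
    out = []
    for i in range(truth.n_subjects):
        S = truth.noiseless_stack(i)
        if truth.noise_sd > 0:
            S = S + truth.noise_sd * rng.standard_normal(S.shape)
        out.append(
            WindowedConnectome(
                data=S,
                n_rois=truth.n_rois,
                window_trs=window_trs,
                step_trs=step_trs,
                tr_seconds=tr_seconds,
                subject_id=f"sub-{i + 1:03d}",
            )
        )
    return out


def shrink_to_positive_definite(
    R: np.ndarray, min_eig: float = 1e-6, tol: float = 1e-6
) -> np.ndarray:
    """Smallest convex shrinkage of R toward identity that is PD.

    Returns (1 - a) R + a I with the smallest a (bisection to ``tol``) whose
    minimum eigenvalue is at least ``min_eig``.
    """
    R = np.asarray(R, dtype=float)

    def _ok(a: float) -> bool:
        M = (1 - a) * R + a * np.eye(R.shape[0])
        return float(np.linalg.eigvalsh(M)[0]) >= min_eig

    if _ok(0.0):
        return R
    lo, hi = 0.0, 1.0
    if not _ok(1.0):
        raise ValueError("cannot reach positive definiteness by shrinkage")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _ok(mid):
            hi = mid
        else:
            lo = mid
    return (1 - hi) * R + hi * np.eye(R.shape[0])


def sample_stationary_series(
    corr: np.ndarray, timepoints: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw a stationary Gaussian series with the given correlation target."""
    R = shrink_to_positive_definite(corr)
    L = np.linalg.cholesky(R)
    return rng.standard_normal((timepoints, R.shape[0])) @ L.T


def synth_roi_timeseries(
    truth: SyntheticTruth,
    timepoints: int = 235,
    tr_seconds: float = 2.0,
    window_trs: int = 30,
    corr_scale: float = 1.0,
) -> list[ROITimeSeries]:
    """Piecewise-stationary ROI series realizing the planted connectivity.

    The series is divided into segments aligned to the window grid; each
    segment's correlation target devectorizes a scaled combination of the
    planted component rows (weights from the subject's atoms, resampled to
    segments), maps z-values through tanh, and is shrunk toward identity
    until positive definite.
    """
    rng = np.random.default_rng([truth.seed, 13])
    n_segments = max(1, timepoints // window_trs)
    bounds = [s * window_trs for s in range(n_segments)] + [timepoints]
    out = []
    for i in range(truth.n_subjects):
        T = truth.T_true[i]
        # resample atom rows onto the segment grid
        rows = np.linspace(0, T.shape[0] - 1, n_segments).round().astype(int)
        series = np.empty((timepoints, truth.n_rois))
        for s in range(n_segments):
            z = corr_scale * (T[rows[s]] @ truth.C_true)
            R = devectorize(np.tanh(z), truth.n_rois)
            np.fill_diagonal(R, 1.0)
            seg = sample_stationary_series(
                R, bounds[s + 1] - bounds[s], rng
            )
            series[bounds[s] : bounds[s + 1]] = seg
        out.append(
            ROITimeSeries(
                data=series,
                tr_seconds=tr_seconds,
                subject_id=f"sub-{i + 1:03d}",
                network_labels=list(truth.network_labels),
            )
        )
    return out
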