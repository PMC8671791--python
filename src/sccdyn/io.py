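"""Reading, extraction and light temporal preprocessing of ROI time series.

Spatial preprocessing (motion correction, normalization, smoothing) is assumed
done upstream; this module covers the steps downstream of a preprocessed 4D
volume or an already-extracted region-by-time table: band-pass filtering in the
low-frequency BOLD range and nuisance (confound) regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "ROITimeSeries",
    "AtlasSpec",
    "read_roi_timeseries",
    "read_atlas_table",
    "dosenbach_atlas",
    "extract_roi_timeseries",
    "bandpass_filter",
    "regress_confounds",
]


@dataclass
class ROITimeSeries:
    """One subject's preprocessed ROI signals, timepoints x ROIs.

    Parameters
    ----------
    data : ndarray, shape (timepoints, n_rois)
    tr_seconds : float
        Repetition time of the acquisition, in seconds.
    subject_id : str
    roi_labels, network_labels : list of str
        One entry per ROI; network labels are free-form (the bundled atlas
        uses CB/CON/DMN/FPN/OCN/SMN).
    motion_summary : float or None
        Externally supplied head-motion QC value (e.g. mean framewise
        displacement in mm); carried as metadata only.
    """

    data: np.ndarray
    tr_seconds: float
    subject_id: str = ""
    roi_labels: list[str] = field(default_factory=list)
    network_labels: list[str] = field(default_factory=list)
    motion_summary: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (timepoints x ROIs)")
        if self.data.shape[0] < 2:
            raise ValueError(
                f"need at least 2 timepoints, got {self.data.shape[0]}"
            )
        if not np.all(np.isfinite(self.data)):
            t, r = np.argwhere(~np.isfinite(self.data))[0]
            raise ValueError(f"non-finite value at timepoint {t}, ROI {r}")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not self.roi_labels:
            self.roi_labels = [f"roi_{i + 1:04d}" for i in range(self.n_rois)]
        if not self.network_labels:
            self.network_labels = ["unknown"] * self.n_rois
        if len(self.roi_labels) != self.n_rois:
            raise ValueError("roi_labels length does not match n_rois")
        if len(self.network_labels) != self.n_rois:
            raise ValueError("network_labels length does not match n_rois")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass
class AtlasSpec:
    """Spherical-ROI atlas: MNI-mm sphere centers with labels and networks."""

    centers_mm: np.ndarray
    radius_mm: float = 6.0
    labels: list[str] = field(default_factory=list)
    networks: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.centers_mm = np.asarray(self.centers_mm, dtype=float)
        if self.centers_mm.ndim != 2 or self.centers_mm.shape[1] != 3:
            raise ValueError("centers_mm must be (n, 3)")
        if not np.all(np.isfinite(self.centers_mm)):
            raise ValueError("atlas centers must be finite")
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        n = len(self.centers_mm)
        if not self.labels:
            self.labels = [f"roi_{i + 1:04d}" for i in range(n)]
        if not self.networks:
            self.networks = ["unknown"] * n
        if len(self.labels) != n or len(self.networks) != n:
            raise ValueError("labels/networks length mismatch")

    def __len__(self) -> int:
        return len(self.centers_mm)


def read_roi_timeseries(
    path: str | Path, tr_seconds: float, subject_id: str | None = None
) -> ROITimeSeries:
    """Read a delimited text file of ROI signals (rows = timepoints).

    An optional single header row provides ROI labels; without it, labels
    default to ``roi_0001`` onward. Both tab- and comma-separated files are
    accepted (sniffed by pandas).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", header=None)
    header = None
    first = df.iloc[0]
    if not pd.to_numeric(first, errors="coerce").notna().all():
        header = [str(v) for v in first]
        df = df.iloc[1:].reset_index(drop=True)
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        t, r = bad[0]
        raise ValueError(
            f"{path}: non-numeric or missing value at row {t}, column {r}"
        )
    if values.shape[0] < 2:
        raise ValueError(f"{path}: need at least 2 timepoint rows")
    return ROITimeSeries(
        data=values,
        tr_seconds=tr_seconds,
        subject_id=subject_id or path.stem,
        roi_labels=header or [],
    )


def read_atlas_table(path: str | Path, radius_mm: float = 6.0) -> AtlasSpec:
    """Read an atlas table (TSV/CSV with columns x, y, z, label, network)."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower(): c for c in df.columns}
    for needed in ("x", "y", "z"):
        if needed not in cols:
            raise ValueError(f"atlas table missing column '{needed}'")
    centers = df[[cols["x"], cols["y"], cols["z"]]].to_numpy(dtype=float)
    labels = (
        [str(v) for v in df[cols["label"]]] if "label" in cols else []
    )
    networks = (
        [str(v) for v in df[cols["network"]]] if "network" in cols else []
    )
    return AtlasSpec(centers, radius_mm, labels, networks)


_DOSENBACH_NET = {
    "cerebellum": "CB",
    "cingulo-opercular": "CON",
    "default": "DMN",
    "fronto-parietal": "FPN",
    "occipital": "OCN",
    "sensorimotor": "SMN",
}


def dosenbach_atlas(radius_mm: float = 6.0) -> AtlasSpec:
    """The 160-sphere meta-analytic atlas grouped into six functional networks.

    Coordinates come from nilearn's bundled table; networks are abbreviated
    CB/CON/DMN/FPN/OCN/SMN.
    """
    from nilearn.datasets import fetch_coords_dosenbach_2010

    d = fetch_coords_dosenbach_2010()
    rois = np.asarray(d.rois)
    if rois.dtype.names:  # recarray variant of older nilearn
        centers = np.column_stack([rois[c] for c in ("x", "y", "z")])
    else:
        centers = rois.astype(float)
    networks = [_DOSENBACH_NET.get(str(n), str(n)) for n in np.asarray(d.networks).ravel()]
    labels = [str(lab) for lab in np.asarray(d.labels).ravel()]
    return AtlasSpec(centers, radius_mm, labels, networks)


def extract_roi_timeseries(
    volume_path: str | Path,
    atlas: AtlasSpec,
    mask_path: str | Path | None = None,
    tr_seconds: float | None = None,
    subject_id: str = "",
) -> ROITimeSeries:
    """Average voxel signals inside each atlas sphere of a 4D volume.

    A voxel belongs to a sphere when its center lies strictly within
    ``radius_mm`` of the sphere center (Euclidean distance in world mm); on
    a 3 mm grid a 6 mm radius centered on a voxel selects the conventional
    27-voxel neighborhood. When a mask image is
    given, only voxels inside the mask contribute (e.g. a gray-matter mask).
    A sphere with no surviving voxels yields an all-zero column and a warning.
    """
    import nibabel as nib

    img = nib.load(str(volume_path))
    affine = img.affine
    if affine is None:
        raise ValueError("volume has no affine; cannot map mm coordinates")
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4D volume")
    nx, ny, nz, nt = data.shape

    mask = None
    if mask_path is not None:
        mimg = nib.load(str(mask_path))
        mask = np.asarray(mimg.dataobj) > 0
        if mask.shape != (nx, ny, nz):
            raise ValueError("mask shape does not match volume grid")

    # world coordinates of every voxel center
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    vox = np.column_stack(
        [ii.ravel(), jj.ravel(), kk.ravel(), np.ones(ii.size)]
    )
    world = (vox @ affine.T)[:, :3]

    out = np.zeros((nt, len(atlas)))
    flat = data.reshape(-1, nt)
    mask_flat = mask.ravel() if mask is not None else None
    for r, center in enumerate(atlas.centers_mm):
        d2 = np.sum((world - center) ** 2, axis=1)
        sel = d2 < atlas.radius_mm**2
        if mask_flat is not None:
            sel &= mask_flat
        if not sel.any():
            warnings.warn(
                f"ROI {atlas.labels[r]!r}: no voxels within "
                f"{atlas.radius_mm} mm (or all masked out); zero signal",
                stacklevel=2,
            )
            continue
        out[:, r] = flat[sel].mean(axis=0)

    if tr_seconds is None:
        zooms = img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return ROITimeSeries(
        data=out,
        tr_seconds=tr_seconds,
        subject_id=subject_id,
        roi_labels=list(atlas.labels),
        network_labels=list(atlas.networks),
    )


def bandpass_filter(
    ts: ROITimeSeries, low_hz: float = 0.01, high_hz: float = 0.08
) -> ROITimeSeries:
    """Zero-phase Butterworth band-pass (order 4 per pass) of every ROI column.

    Defaults to the conventional 0.01-0.08 Hz resting-state BOLD band. The
    forward-backward pass removes the mean, so output columns are ~zero-mean.
    """
    nyq = 1.0 / (2.0 * ts.tr_seconds)
    if not (0 < low_hz < high_hz):
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyq:
        raise ValueError(
            f"high_hz={high_hz} must be below the Nyquist frequency {nyq}"
        )
    sos = sps.butter(4, [low_hz / nyq, high_hz / nyq], btype="band", output="sos")
    filtered = sps.sosfiltfilt(sos, ts.data, axis=0)
    return replace(ts, data=np.ascontiguousarray(filtered))


def regress_confounds(
    ts: ROITimeSeries,
    confounds: np.ndarray | None = None,
    add_derivatives: bool = False,
) -> ROITimeSeries:
    """Residualize ROI signals on nuisance regressors by least squares.

    An intercept column is always included, so the output is at least
    demeaned. ``add_derivatives`` appends backward temporal differences of
    each confound (first row zero), the usual treatment of motion/CSF/WM
    "first-order derivative" regressors. Collinear confound columns are
    dropped with a warning rather than failing.
    """
    n = ts.n_timepoints
    design = [np.ones((n, 1))]
    if confounds is not None and np.size(confounds):
        conf = np.asarray(confounds, dtype=float)
        if conf.ndim == 1:
            conf = conf[:, None]
        if conf.shape[0] != n:
            raise ValueError(
                f"confounds have {conf.shape[0]} rows, expected {n}"
            )
        if not np.all(np.isfinite(conf)):
            raise ValueError("confounds contain non-finite values")
        design.append(conf)
        if add_derivatives:
            deriv = np.diff(conf, axis=0, prepend=conf[:1])
            design.append(deriv)
    X = np.column_stack(design)

    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} collinear confound column(s)",
            stacklevel=2,
        )
        X = X[:, keep]
        q, _ = np.linalg.qr(X)
    resid = ts.data - q @ (q.T @ ts.data)
    return replace(ts, data=resid)
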