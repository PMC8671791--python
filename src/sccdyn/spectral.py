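"""Frequency-domain diagnostics of the component-based reconstruction.

Each edge's windowed connectivity values form a time series sampled once per
window step. Comparing the spectra of the original, reconstructed, and
residual series shows where in frequency the reconstruction lives: the
sliding window acts as a low-pass filter on connectivity dynamics with an
effective cutoff near 1/window-length Hz, so a good low-rank reconstruction
retains the power below that cutoff and sheds the (mostly noise) power above
it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dfc import WindowedConnectome

__all__ = ["SpectraReport", "connectivity_spectra", "band_power"]


@dataclass
class SpectraReport:
    """Median one-sided power spectra of original/reconstructed/residual."""

    freqs: np.ndarray  # Hz
    median_power_original: np.ndarray
    median_power_reconstructed: np.ndarray
    median_power_residual: np.ndarray
    cutoff_hz: float


def _edge_power(X: np.ndarray) -> np.ndarray:
    """One-sided power per edge of demeaned series (w x p) -> (nf x p)."""
    Xd = X - X.mean(axis=0, keepdims=True)
    F = np.fft.rfft(Xd, axis=0)
    return np.abs(F) ** 2


def connectivity_spectra(
    original: WindowedConnectome, reconstructed: np.ndarray
) -> SpectraReport:
    """Median-across-edges spectra of original, reconstructed and residual.

    The residual is the element-wise difference original - reconstructed.
    Series are demeaned per edge before the FFT so the DC bin reflects only
    the removed mean; the sampling interval is one window step
    (step_trs x tr_seconds) and the reported cutoff is 1/window-length Hz.
    """
    S = np.asarray(original.data, dtype=float)
    R = np.asarray(reconstructed, dtype=float)
    if S.shape != R.shape:
        raise ValueError("original and reconstructed shapes differ")
    w = S.shape[0]
    if w < 4:
        raise ValueError("need at least 4 windows for a spectrum")
    dt = original.step_seconds
    freqs = np.fft.rfftfreq(w, d=dt)
    p_orig = _edge_power(S)
    p_rec = _edge_power(R)
    p_res = _edge_power(S - R)
    return SpectraReport(
        freqs=freqs,
        median_power_original=np.median(p_orig, axis=1),
        median_power_reconstructed=np.median(p_rec, axis=1),
        median_power_residual=np.median(p_res, axis=1),
        cutoff_hz=1.0 / original.window_seconds,
    )


def band_power(report: SpectraReport, low_hz: float, high_hz: float | None = None,
               which: str = "original") -> float:
    """Total median power in [low_hz, high_hz] (high defaults to Nyquist)."""
    power = {
        "original": report.median_power_original,
        "reconstructed": report.median_power_reconstructed,
        "residual": report.median_power_residual,
    }[which]
    hi = high_hz if high_hz is not None else np.inf
    sel = (report.freqs >= low_hz) & (report.freqs <= hi)
    return float(power[sel].sum())
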