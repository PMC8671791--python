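"""From ROI time series to windowed Fisher-z connectivity.

Simulates piecewise-stationary ROI series from a planted truth, applies the
standard temporal preprocessing (0.01-0.08 Hz band-pass, confound
regression), and estimates sliding-window dynamic functional connectivity.
"""

import numpy as np

import sccdyn as sd

truth = sd.make_ground_truth(
    n_rois=12, n_networks=4, k_star=2, sparsity=0.2,
    n_subjects=1, w=10, seed=5,
)
(ts,) = sd.synth_roi_timeseries(truth, timepoints=240, tr_seconds=2.0,
                                corr_scale=4.0)
print(f"ROI series: {ts.n_timepoints} volumes x {ts.n_rois} ROIs, "
      f"TR {ts.tr_seconds} s")

ts = sd.bandpass_filter(ts, 0.01, 0.08)
confounds = np.random.default_rng(0).standard_normal((ts.n_timepoints, 3))
ts = sd.regress_confounds(ts, confounds, add_derivatives=True)
print(f"after band-pass + confound regression: column means ~ "
      f"{np.abs(ts.data.mean(axis=0)).max():.2e}")

wc = sd.sliding_window_dfc(ts, window_trs=30, step_trs=2)
print(f"dFC stack: {wc.n_windows} windows x {wc.n_edges} edges "
      f"(window {wc.window_seconds:.0f} s, step {wc.step_seconds:.0f} s)")
print(f"Fisher-z range: [{wc.data.min():.2f}, {wc.data.max():.2f}]")
# each row is one window's vectorized upper-triangle correlation matrix,
# the input representation for the sparse decomposition
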