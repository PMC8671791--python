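import numpy as np
import pytest

import sccdyn as sd


@pytest.fixture(scope="session")
def small_truth():
    """Small planted decomposition shared across fast tests."""
    return sd.make_ground_truth(
        n_rois=12, n_networks=4, k_star=3, sparsity=0.2,
        n_subjects=6, w=24, target_snr=50.0, seed=11,
    )


@pytest.fixture(scope="session")
def small_stacks(small_truth):
    return sd.synth_windowed_stack(small_truth)


@pytest.fixture(scope="session")
def small_stack(small_stacks):
    return sd.concatenate_subjects(small_stacks)


@pytest.fixture(scope="session")
def small_fit(small_stack):
    return sd.learn_group_sccs(small_stack, k=3, lambda_=0.02, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_roi_ts(rng, n_timepoints=80, n_rois=5, tr=2.0):
    return sd.ROITimeSeries(
        data=rng.standard_normal((n_timepoints, n_rois)),
        tr_seconds=tr,
        subject_id="rand",
    )
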