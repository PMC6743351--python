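import numpy as np
import pytest

import nirsmarkers as nm


@pytest.fixture(scope="session")
def epoch_grid():
    """Default [-10, +70] s epoch time grid at the device sampling rate."""
    return nm.epoch_times(nm.ParadigmSpec(), nm.DEFAULT_FS)


@pytest.fixture(scope="session")
def default_design(epoch_grid):
    return nm.build_design(epoch_grid)


@pytest.fixture(scope="session")
def small_cohort():
    """3+3 subject cohort, one task, default noise; generated once."""
    spec = nm.CohortSpec(n_mci=3, n_hc=3, seed=11)
    raws, hemos, truth = nm.generate_cohort(spec, tasks=("N-back",))
    return spec, raws, hemos, truth


@pytest.fixture(scope="session")
def layout():
    return nm.default_layout()


def make_epochs(hbo, hbr=None, times=None, fs=nm.DEFAULT_FS, **meta):
    """Build an EpochSet from raw arrays (trials, channels, samples)."""
    hbo = np.asarray(hbo, dtype=float)
    if hbr is None:
        hbr = -hbo / 3.0
    if times is None:
        times = -10.0 + np.arange(hbo.shape[2]) / fs
    return nm.EpochSet(hbo=hbo, hbr=np.asarray(hbr, dtype=float),
                       times=np.asarray(times, dtype=float), fs=fs, **meta)
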