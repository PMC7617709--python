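import numpy as np
import pytest

from tmseegkit.data_model import Cell, EpochedEEG
from tmseegkit.montage import default_montage
from tmseegkit.synth_data import CohortConfig, synth_tep_cohort


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny null TMS cohort shared by several test modules."""
    cfg = CohortConfig(n_subjects=5, n_trials=4, srate=500.0, seed=11)
    return synth_tep_cohort(cfg)


@pytest.fixture(scope="session")
def effect_cohort():
    """Cohort with an injected N100 reduction after active stimulation."""
    cfg = CohortConfig(
        n_subjects=8, n_trials=6, srate=500.0, seed=7,
        n100_post_delta={"active": 3.0, "sham": 2.5},
        noise_sd=0.5,
    )
    return synth_tep_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_epochs(data, srate=1000.0, t0_index=None, montage_=None, cell=None):
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[:, :, None]
    n_ch = data.shape[0]
    if montage_ is None:
        montage_ = default_montage(default_montage().names[:n_ch])
    if t0_index is None:
        t0_index = data.shape[1] // 2
    return EpochedEEG(data, srate, t0_index, montage_, cell)


@pytest.fixture
def epochs_factory():
    return make_epochs
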