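import numpy as np
import pytest

from emct2 import (
    PhantomSpec,
    SequenceParams,
    build_dictionary,
    build_grid,
    make_study,
)
from emct2.pipeline import fit_study


@pytest.fixture(scope="session")
def seq() -> SequenceParams:
    """The study MESE protocol: TR 2057 ms, 10 echoes at 5.9 ms, 90/125 deg."""
    return SequenceParams()


@pytest.fixture(scope="session")
def full_dict(seq):
    """Full default dictionary: T2 1-300 ms x B1 60-140%, 24,300 atoms."""
    return build_dictionary(build_grid(), seq)


@pytest.fixture(scope="session")
def small_grid_kwargs() -> dict:
    """Reduced grid for fast pipeline-level tests (same step sizes)."""
    return dict(t2_min=20.0, t2_max=80.0, t2_step=1.0,
                b1_min=0.90, b1_max=1.10, b1_step=0.01)


@pytest.fixture(scope="session")
def noisy_study(seq):
    """Full-size synthetic study at the study conditions: 11 bilateral
    participants, 3 dropped knees, Rician noise at first-echo SNR 50,
    global -2% run effect with full recovery at control."""
    spec = PhantomSpec(noise_model="rician", snr=50.0, seed=11)
    return make_study(spec, n_participants=11, dropout_knees=3, seq=seq)


@pytest.fixture(scope="session")
def noisy_rois(noisy_study, full_dict):
    """Dictionary-fitted ROI table for the noisy study (57 samples)."""
    return fit_study(noisy_study, full_dict)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20250823)
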