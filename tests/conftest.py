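import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

from ivbm import (
    SimulationConfig,
    default_atlas_spec,
    fit_references,
    hc_calibration,
    make_atlas,
    score_subjects,
    simulate_study,
)


@pytest.fixture(scope="session")
def atlas():
    return make_atlas(default_atlas_spec())


@pytest.fixture(scope="session")
def calibration():
    """200 reference HC + 50 held-out HC on the default 32-cube grid."""
    return hc_calibration(n_reference=200, n_test=50, seed=1234)


@pytest.fixture(scope="session")
def default_study():
    """One full study at the study-scale group sizes (48/96/12+6/20)."""
    return simulate_study(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def default_references(default_study):
    return fit_references(default_study)


@pytest.fixture(scope="session")
def default_scores(default_study, default_references):
    roi_table, index_table = score_subjects(default_study, default_references)
    return roi_table, index_table


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
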