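import pytest

from nmdx import default_config, simulate_cohort
from nmdx.dmd import DmdExonModel
from nmdx.io import load_panels


@pytest.fixture(scope="session")
def exon_model():
    return DmdExonModel.load()


@pytest.fixture(scope="session")
def panels():
    return load_panels()


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-proband synthetic cohort with planted truth (fixed seed)."""
    return simulate_cohort(default_config(n_probands=120, seed=42))


@pytest.fixture(scope="session")
def medium_cohort():
    """A 500-proband synthetic cohort used for recovery checks."""
    return simulate_cohort(default_config(n_probands=500, seed=7))
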