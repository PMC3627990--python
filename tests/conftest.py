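import numpy as np
import pytest

from apistrack.pipeline import make_fixtures


@pytest.fixture(scope="session")
def fixtures():
    """Canonical hand traces and a short-session 8-bee cohort (seed 1)."""
    return make_fixtures(seed=1)


@pytest.fixture(scope="session")
def small_cohort(fixtures):
    return fixtures["cohort"]


@pytest.fixture(scope="session")
def stim_event(fixtures):
    return fixtures["event"]


@pytest.fixture
def rng():
    return np.random.default_rng(20230417)
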