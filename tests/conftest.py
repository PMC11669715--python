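import numpy as np
import pytest

from gstnull.cohort import load_cohort_fixture, load_gst_panel_fixture


@pytest.fixture(scope="session")
def cohort():
    return load_cohort_fixture()


@pytest.fixture(scope="session")
def panel():
    return load_gst_panel_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)
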