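import numpy as np
import pytest

from diskfret.io import read_component_table
from diskfret.pipeline import default_table_path
from diskfret.synth import DecayComponentSet, InstrumentResponse


@pytest.fixture(scope="session")
def component_table():
    return read_component_table(default_table_path())


@pytest.fixture
def irf():
    return InstrumentResponse(fwhm_ps=150.0, t0_ns=2.0)


@pytest.fixture
def coupled_truth():
    """Biexponential truth of the coupled donor-acceptor sample, with a
    realistic dark-count floor."""
    return DecayComponentSet(
        components=((0.3582, 0.86), (0.6418, 4.39)),
        background_fraction=0.05,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
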