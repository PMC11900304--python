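import numpy as np
import pytest

from tearmrm.synthetic import StudyDesign
from tearmrm.transitions import bundled_panel, bundled_reference_table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def reference_table():
    return bundled_reference_table()


@pytest.fixture(scope="session")
def panel():
    return bundled_panel()


@pytest.fixture
def default_design():
    return StudyDesign()


@pytest.fixture
def noiseless_design():
    return StudyDesign().noiseless()
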