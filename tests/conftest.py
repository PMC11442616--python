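import numpy as np
import pytest

from dtialps.phantom import (build_phantom_tensors, default_gradient_table,
                             default_phantom_spec, simulate_signal)
from dtialps.study import load_control_table, load_patient_table
from dtialps.tensor import fit_log_linear


@pytest.fixture(scope="session")
def scheme64():
    """The shipped 65-entry scheme (1 x b=0 + 64 x b=1000)."""
    return default_gradient_table()


@pytest.fixture(scope="session")
def phantom_truth():
    return build_phantom_tensors(default_phantom_spec("contralateral"))


@pytest.fixture(scope="session")
def noiseless_dwi(phantom_truth, scheme64):
    return simulate_signal(phantom_truth, scheme64)


@pytest.fixture(scope="session")
def fitted_field(noiseless_dwi, scheme64):
    return fit_log_linear(noiseless_dwi, scheme64)


@pytest.fixture(scope="session")
def patients():
    return load_patient_table()


@pytest.fixture(scope="session")
def controls():
    return load_control_table()


@pytest.fixture(scope="session")
def included(patients):
    return [p for p in patients if p.included]


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
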