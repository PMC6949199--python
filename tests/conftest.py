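import numpy as np
import pytest

from qdect.calibration import CoefficientMatrix
from qdect.decomposition import MaterialDecomposition
from qdect.synthetic import generate_phantom_table


@pytest.fixture(scope="session")
def example_coeffs():
    """Hand-picked, well-conditioned coefficient matrix for arithmetic tests."""
    return CoefficientMatrix(mu_i_32=0.45, mu_i_34=0.95, mu_gd_32=0.70, mu_gd_34=0.65)


@pytest.fixture(scope="session")
def noiseless_coeffs():
    """Coefficients calibrated from a noiseless synthetic phantom table."""
    table = generate_phantom_table(noise_sigma=0.0, rng=np.random.default_rng(0))
    return MaterialDecomposition().fit(table).coeffs_


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
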