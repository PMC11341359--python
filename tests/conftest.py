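import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from impurisk.epitope_scan import calibrate, default_matrices
from impurisk.fixtures import api_peptide
from impurisk.synthetic_data import gen_background_peptides


@pytest.fixture(scope="session")
def matrices():
    """Default synthetic panel calibrated on a 12,000-frame background."""
    m = default_matrices(seed=123)
    background = gen_background_peptides(1200, 18, seed=1)
    return calibrate(m, background)


@pytest.fixture(scope="session")
def held_out_background():
    """Background peptides never used in calibration (11,000 frames)."""
    return gen_background_peptides(1000, 19, seed=2)


@pytest.fixture(scope="session")
def api():
    return api_peptide()


def crafted_matrix_for(ninemer: str) -> np.ndarray:
    """A 9x20 matrix whose unique top-scoring frame is ``ninemer``."""
    from impurisk.epitope_scan import _AA_INDEX

    m = np.zeros((9, 20))
    for pos, aa in enumerate(ninemer):
        m[pos, _AA_INDEX[aa]] = 10.0
    return m
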