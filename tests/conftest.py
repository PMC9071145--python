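import numpy as np
import pytest

import perceptqa as pq


@pytest.fixture(scope="session")
def grid256():
    return pq.build_fourier_grid(256)


@pytest.fixture(scope="session")
def grid128():
    return pq.build_fourier_grid(128)


@pytest.fixture(scope="session")
def images128():
    """Small set of 1/f surrogates at the reduced test resolution."""
    return pq.synth_image_set(6, size=128, alpha=-1.45, contrast_db=21.0, seed=42)


@pytest.fixture(scope="session")
def pool128():
    """Image pool large enough for 50-trial 2AFC blocks."""
    return pq.synth_image_set(110, size=128, alpha=-1.45, contrast_db=21.0, seed=42)


@pytest.fixture(scope="session")
def bank128():
    return pq.FilterBank(pq.FilterBankConfig(size=128, n_scales=5,
                                             omega=1.43, orient_fwhh=22.5))
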