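import numpy as np
import pytest

from mechanospec.clustering import spectra_matrix
from mechanospec.pipeline import prep_raman_map
from mechanospec.synthetic import generate_phantom_map, u87_line_config


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def u87_small_dataset():
    """Four U87-like line maps (200 co-localized points), preprocessed.

    Shared across clustering/statistics tests to avoid regenerating the
    phantom; returns (maps, matrix, wavenumber axis, true labels).
    """
    maps = [generate_phantom_map(u87_line_config(seed=300 + i))
            for i in range(4)]
    raman = [s for m in maps for s in m.raman]
    truth = [lab for m in maps for lab in m.labels]
    mat, axis = spectra_matrix(prep_raman_map(raman))
    return maps, mat, axis, truth
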