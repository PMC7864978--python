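import numpy as np
import pytest

from pgxancestry import synthetic_data as sd
from pgxancestry.core_io import GenotypeMatrix


@pytest.fixture(scope="session")
def small_sim():
    """Desk-scale synthetic dataset shared across test modules."""
    cfg = sd.default_config(seed=7, n_per_population=20, n_loci=3000)
    return sd.simulate_dataset(cfg)


@pytest.fixture
def toy_gm():
    """3 samples x 4 variants with one missing genotype."""
    dosage = np.array(
        [
            [0, 1, 2, 0],
            [1, 1, 2, -1],
            [2, 1, 0, 2],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(["s1", "s2", "s3"], ["v1", "v2", "v3", "v4"], dosage)
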