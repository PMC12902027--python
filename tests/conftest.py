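import numpy as np
import pytest

from accesshist import EpitopeClassSet, NoiseSpec, generate_series
from accesshist.synthetic import fourfold_dilutions


@pytest.fixture(scope="session")
def single_class():
    return EpitopeClassSet.from_pairs([(1.0, 1e-4)])


@pytest.fixture(scope="session")
def fourfold_ladder():
    """16 four-fold dilutions of a 1:100 stock."""
    return fourfold_dilutions(1e-2, 16)


@pytest.fixture(scope="session")
def noisy_single_series(single_class, fourfold_ladder):
    """Replicate series with 10% CV, 8 replicates, fixed seed."""
    return generate_series(single_class, fourfold_ladder, NoiseSpec(replicates=8, cv=0.1, seed=1)).series
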