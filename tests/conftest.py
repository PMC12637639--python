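import numpy as np
import pytest

from hicgat.io_formats import GenomicLocus
from hicgat.polymer_null import build_ensemble_null


@pytest.fixture(scope="session")
def small_null():
    """Shared small chain ensemble (fast; 60 beads, 300 chains)."""
    return build_ensemble_null(300, 60, seed=11)


@pytest.fixture(scope="session")
def small_null_chains():
    """Small ensemble with its chains kept for brute-force oracles."""
    return build_ensemble_null(50, 40, seed=13, return_chains=True)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def window_4mb():
    return GenomicLocus("chr9", 0, 4_000_000)
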