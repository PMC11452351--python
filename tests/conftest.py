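import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from sweepscan.matrix import HaplotypeMatrix


def random_matrix(n=16, m=60, seed=0, p=0.35):
    """Small random haplotype fixture with irregular genetic gaps."""
    rng = np.random.default_rng(seed)
    alleles = (rng.random((n, m)) < p).astype(np.uint8)
    # keep every site polymorphic so no class is empty by accident
    for col in range(m):
        if alleles[:, col].sum() == 0:
            alleles[rng.integers(n), col] = 1
        elif alleles[:, col].sum() == n:
            alleles[rng.integers(n), col] = 0
    phys = np.sort(rng.choice(np.arange(1, 10 * m), size=m, replace=False)).astype(float)
    gen = np.cumsum(rng.random(m) * 0.01)
    return HaplotypeMatrix(alleles, phys, gen)


@pytest.fixture
def small_hm():
    return random_matrix(seed=1)


@pytest.fixture(scope="session")
def neutral_equilibrium_hm():
    """One mid-sized neutral equilibrium segment shared across tests."""
    from sweepscan import simulate

    return simulate.simulate_neutral(simulate.equilibrium(), 200, length=3e5, seed=42)
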