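import numpy as np
import pytest

from enksim.genome import GenomeMap
from enksim.landscape import build_enk_model, build_nk_submodel


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def gmap():
    return GenomeMap()


@pytest.fixture(scope="session")
def enk_k6():
    """One medium-complexity ensemble shared across read-only tests."""
    return build_enk_model(6, master_seed=42)


@pytest.fixture(scope="session")
def additive_submodel():
    return build_nk_submodel(500, 1, np.random.default_rng(5))


def all_genotypes(n_loci: int) -> np.ndarray:
    """All 3^n dosage vectors, for brute-force oracles on tiny landscapes."""
    grids = np.meshgrid(*([np.arange(3)] * n_loci), indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)
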