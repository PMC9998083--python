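import numpy as np
import pytest

from triomr import synthetic_data as sd
from triomr.instruments import ld_from_genotypes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_triplet_study(seed: int):
    """Planted-chain study (alpha_TM=0.3, alpha_MP=0.2, direct=0) plus LD."""
    truth = sd.triplet_truth(seed=seed)
    panel = sd.generate_reference_panel(
        n_samples=1000, n_snps=120, ld_block_size=1, seed=seed,
    )
    study = sd.generate_multiomics_sumstats(panel, truth, seed=seed)
    ld = ld_from_genotypes(panel.dosages)
    return study, ld


@pytest.fixture(scope="session")
def triplet_study():
    return make_triplet_study(seed=7)


@pytest.fixture(scope="session")
def noiseless_study():
    truth = sd.triplet_truth(seed=3)
    panel = sd.generate_reference_panel(
        n_samples=1000, n_snps=120, ld_block_size=1, seed=3,
    )
    study = sd.generate_multiomics_sumstats(panel, truth, seed=3, noise=False)
    ld = ld_from_genotypes(panel.dosages)
    return study, ld
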