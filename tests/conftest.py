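import numpy as np
import pytest

from cgsa import gene_set_kernels, simulate_genotypes


@pytest.fixture(scope="session")
def small_panel():
    """60 individuals x 30 SNPs, HWE, no missingness."""
    return simulate_genotypes(60, 30, maf_range=(0.1, 0.5), seed=11)


@pytest.fixture(scope="session")
def small_kernels(small_panel):
    return gene_set_kernels(small_panel)


@pytest.fixture(scope="session")
def tiny_panel():
    """4 individuals x 20 SNPs for brute-force pairwise oracles."""
    return simulate_genotypes(4, 20, maf_range=(0.2, 0.5), seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
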