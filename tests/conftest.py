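import numpy as np
import pytest

from ploidpop import (
    AlleleCountMatrix,
    SimConfig,
    call_diploid,
    call_pseudo_haploid,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """Compact synthetic cohort for fast unit tests."""
    return simulate_dataset(SimConfig(n_loci=300, samples_per_pool=4, seed=11))


@pytest.fixture(scope="session")
def default_dataset():
    """Cohort at the generator's default study design."""
    return simulate_dataset(SimConfig(seed=3))


@pytest.fixture(scope="session")
def small_diploid(small_dataset):
    return call_diploid(small_dataset.counts)


@pytest.fixture(scope="session")
def small_pseudo_haploid(small_dataset):
    return call_pseudo_haploid(small_dataset.counts, seed=42)


@pytest.fixture()
def tiny_counts():
    """Hand-sized allele-count matrix covering all diploid call classes."""
    a = np.array([[5, 0, 1, 6, 0, 2], [0, 0, 1, 0, 3, 7]])
    b = np.array([[0, 0, 1, 0, 7, 3], [4, 0, 2, 6, 0, 0]])
    return AlleleCountMatrix(
        a, b, ["s1", "s2"], [f"L{i:03d}:0" for i in range(6)]
    )
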