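import numpy as np
import pytest

from sgskit import GenotypeDataset, IBDSimParams, SpatialCoordinates, simulate_ibd_population


def make_dataset(calls, pops=None, clusters=None, loci=None):
    calls = np.asarray(calls, dtype=np.int64)
    n, L = calls.shape[:2]
    return GenotypeDataset(
        individual_ids=[f"i{k}" for k in range(n)],
        loci=loci or [f"L{j}" for j in range(L)],
        calls=calls,
        population_labels=pops,
        cluster_labels=clusters,
    )


def random_hwe_dataset(rng, n, freqs_per_locus):
    """Genotypes drawn locus-wise iid from given allele frequencies (HWE)."""
    calls = np.empty((n, len(freqs_per_locus), 2), dtype=np.int64)
    for j, freqs in enumerate(freqs_per_locus):
        alleles = np.arange(1, len(freqs) + 1)
        calls[:, j, :] = rng.choice(alleles, size=(n, 2), p=freqs)
    return make_dataset(calls)


def random_coords(rng, n, extent=1000.0):
    return SpatialCoordinates(
        individual_ids=[f"i{k}" for k in range(n)],
        x=rng.uniform(0, extent, n),
        y=rng.uniform(0, extent, n),
    )


@pytest.fixture(scope="session")
def small_ibd_sim():
    """One fast IBD simulation shared across tests (strong structure)."""
    params = IBDSimParams(
        habitat_side=400.0,
        census_density_D=25.0,
        sigma_seed=12.0,
        sigma_pollen=12.0,
        n_loci=8,
        n_generations=60,
        sample_size=60,
        rng_seed=11,
    )
    return simulate_ibd_population(params)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
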