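import numpy as np
import pytest

from pgx_exposure.catalog import load_catalog
from pgx_exposure.genotypes_io import CohortGenotypes
from pgx_exposure.synthetic_data import SimulationConfig, simulate_cohort

# fixed once for every stochastic check in the suite
SEED = 20190702


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def cohort498(catalog):
    """Phased synthetic cohort at the reference-study size (n=498)."""
    return simulate_cohort(SimulationConfig(n_individuals=498, seed=SEED), catalog)


@pytest.fixture(scope="session")
def cohort498_unphased(catalog):
    return simulate_cohort(
        SimulationConfig(n_individuals=498, seed=SEED, phased_output=False), catalog
    )


def make_cohort(catalog, genotypes, phased=True, sample_ids=None, copy_number=None):
    """Build a small in-memory cohort from {rsid: [(h1, h2), ...]} genotypes.

    Unlisted catalog variants default to homozygous reference.
    """
    n = len(next(iter(genotypes.values())))
    sample_ids = sample_ids or [f"X{i}" for i in range(n)]
    rsids = []
    for gene in catalog.genes.values():
        for r in gene.defining_rsids:
            if r not in rsids:
                rsids.append(r)
    hap1 = np.zeros((n, len(rsids)), dtype=np.int8)
    hap2 = np.zeros((n, len(rsids)), dtype=np.int8)
    for rsid, pairs in genotypes.items():
        j = rsids.index(rsid)
        for i, (a, b) in enumerate(pairs):
            hap1[i, j] = a
            hap2[i, j] = b
    return CohortGenotypes(
        sample_ids=sample_ids,
        sites=[catalog.sites[r] for r in rsids],
        hap1=hap1,
        hap2=hap2,
        phased=np.full(len(rsids), bool(phased)),
        copy_number=copy_number or {},
    )
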