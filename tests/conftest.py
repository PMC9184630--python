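import numpy as np
import pandas as pd
import pytest

from timberdna.genodata_io import MISSING, GenotypeTable
from timberdna.synthetic_data import CpSimConfig, SimConfig, simulate_cpdna, simulate_hierarchical_ssr


def make_gt(genotypes_per_locus: dict[str, list[tuple[int, int]]], populations=None, regions=None):
    """Build a small GenotypeTable from literal genotype lists."""
    loci = list(genotypes_per_locus)
    n = len(next(iter(genotypes_per_locus.values())))
    populations = populations or ["pop1"] * n
    regions = regions or [None] * n
    samples = pd.DataFrame(
        {"sample_id": [f"s{i + 1}" for i in range(n)], "population": populations, "region": regions}
    )
    genos = {loc: np.array(pairs, dtype=np.int64) for loc, pairs in genotypes_per_locus.items()}
    return GenotypeTable(samples=samples, loci=loci, genotypes=genos)


@pytest.fixture(scope="session")
def structured_gt():
    """Two regions x four populations with realistic theta/f, fixed seed."""
    return simulate_hierarchical_ssr(
        SimConfig(
            n_regions=2, pops_per_region=4, n_per_pop=25, n_loci=10, alleles_per_locus=10,
            theta_region=0.08, theta_pop=0.05, f_inbreed=0.08, seed=11,
        )
    )


@pytest.fixture(scope="session")
def cp_bundle():
    """Default four-marker cpDNA simulation with truth labels."""
    cfg = CpSimConfig(seed=7)
    return cfg, *simulate_cpdna(cfg, regions=["Region A", "Region B"])
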