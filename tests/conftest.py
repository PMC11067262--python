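import numpy as np
import pandas as pd
import pytest

from hla_phenoscope import synthetic_data as sd
from hla_phenoscope.io_qc import GenotypeMatrix


@pytest.fixture(scope="session")
def easy_pool():
    return sd.simulate_reference_pool(**sd.easy_preset(seed=11))


@pytest.fixture(scope="session")
def easy_cohort(easy_pool):
    """n=600 cohort from the strong-LD pool (shared across modules)."""
    return sd.simulate_cohort(easy_pool, 600, seed=12)


@pytest.fixture(scope="session")
def perfect_pool():
    """Deterministic tagging: every allele exactly predicted by its signature."""
    return sd.simulate_reference_pool(
        n_haplotypes=200, n_snps=16, alleles_per_gene=2,
        tagging_strength=1.0, seed=1, genes=("HLA-A",))


@pytest.fixture(scope="session")
def perfect_cohort(perfect_pool):
    return sd.simulate_cohort(perfect_pool, 150, seed=2)


@pytest.fixture
def tiny_gm():
    """3 samples x 4 variants, one missing genotype, chr6 MHC positions."""
    variants = pd.DataFrame({
        "chrom": ["6"] * 4,
        "pos": [28_510_120, 29_000_000, 33_480_577, 33_480_578],
        "id": ["v1", "v2", "v3", "v4"],
        "ref": ["A", "C", "G", "T"],
        "alt": ["G", "T", "A", "C"],
    })
    dosage = np.array([
        [0.0, 1.0, 2.0, 0.0],
        [1.0, np.nan, 0.0, 1.0],
        [2.0, 0.0, 1.0, 2.0],
    ])
    return GenotypeMatrix(samples=["s1", "s2", "s3"], variants=variants,
                          dosage=dosage)
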