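import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from sccadmix.data import GenotypeData
from sccadmix.simulate import default_study, simulate_study

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def admixed_study():
    """One moderate admixed cohort shared by read-only tests."""
    design = default_study("admixed", n_individuals=1500, seed=11)
    return design, simulate_study(design)


@pytest.fixture(scope="session")
def small_study():
    """A small, fast cohort for structural tests."""
    design = default_study("admixed", n_individuals=300, seed=5, n_neutral=100)
    return design, simulate_study(design)


def make_genotypes(dosages, haplotypes=None, prefix="v"):
    """GenotypeData from a raw dosage matrix (one chromosome, 1 Mb grid)."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    variants = pd.DataFrame(
        {
            "variant_id": [f"{prefix}{j + 1}" for j in range(m)],
            "chrom": "1",
            "pos": (np.arange(m) + 1) * 1_000_000,
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeData(
        samples=[f"s{i + 1}" for i in range(n)],
        variants=variants,
        dosages=dosages,
        haplotypes=haplotypes,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
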