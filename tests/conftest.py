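import numpy as np
import pandas as pd
import pytest

from crossase import phasing, synthetic
from crossase.genotypes import GenotypeMatrix


def matrix_from_codes(codes, depth=None, samples=None, breeds=None) -> GenotypeMatrix:
    """Build a small GenotypeMatrix from a (samples x loci) code array."""
    codes = np.asarray(codes, dtype=np.int8)
    n_samples, n_loci = codes.shape
    if samples is None:
        samples = [f"S{i + 1}" for i in range(n_samples)]
    loci = pd.DataFrame(
        {
            "chrom": "1",
            "pos": (np.arange(n_loci) + 1) * 100,
            "ref": "A",
            "alt": "G",
            "depth": depth if depth is not None else 30,
        }
    )
    return GenotypeMatrix(loci=loci, samples=samples, genotypes=codes, breeds=breeds)


def freq_table(D, L, Y) -> pd.DataFrame:
    """Wide transmitted-allele-frequency table for given per-locus D/L/Y."""
    D, L, Y = (np.atleast_1d(np.asarray(x, dtype=float)) for x in (D, L, Y))
    n = len(D)
    return pd.DataFrame(
        {
            "chrom": "1",
            "pos": (np.arange(n) + 1) * 100,
            "ref": "A",
            "alt": "G",
            "D": D,
            "L": L,
            "Y": Y,
        }
    )


@pytest.fixture(scope="session")
def default_freqs() -> pd.DataFrame:
    model = synthetic.BreedModel(n_loci=30_000, seed=11)
    return synthetic.simulate_breed_frequencies(model)


@pytest.fixture(scope="session")
def family(default_freqs) -> synthetic.FamilyTruth:
    return synthetic.simulate_dly_family(default_freqs, seed=12)


@pytest.fixture(scope="session")
def phased_family(family) -> phasing.PhasedFamily:
    return phasing.phase_family(family.matrix, family.pedigree)
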