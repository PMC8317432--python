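import numpy as np
import pytest

import tetrapop as tp
from tetrapop.genotyping import GenotypeMatrix


def genotypes_from_dosage(dosage: np.ndarray) -> GenotypeMatrix:
    """Wrap a true dosage matrix as a fully-called GenotypeMatrix."""
    dosage = np.asarray(dosage, dtype=int)
    n, s = dosage.shape
    return GenotypeMatrix(
        dosage=dosage,
        posterior_max=np.ones_like(dosage, dtype=float),
        individual_ids=[f"ind{i + 1}" for i in range(n)],
        site_ids=[f"site{j + 1}" for j in range(s)],
    )


@pytest.fixture(scope="session")
def tet_dataset():
    """Default tetrasomic landscape: 16 localities x 9, 2,000 loci, 16x."""
    truth, reads = tp.simulate_dataset(
        n_localities=16, n_per_pop=9, n_loci=2000, seed=20240101
    )
    genotypes, site_info = tp.call_genotypes(reads)
    return truth, reads, genotypes, site_info


@pytest.fixture(scope="session")
def dis_dataset():
    """Fully disomic (fixed subgenome difference) counterpart."""
    truth, reads = tp.simulate_dataset(
        n_localities=16,
        n_per_pop=9,
        n_loci=2000,
        mode="disomic",
        subgenome_divergence=1.0,
        seed=20240202,
    )
    genotypes, site_info = tp.call_genotypes(reads)
    return truth, reads, genotypes, site_info


def truth_site_indices(genotypes) -> np.ndarray:
    """Column indices into the truth matrices for retained sites."""
    return np.array([int(s.removeprefix("site")) - 1 for s in genotypes.site_ids])
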