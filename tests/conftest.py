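import numpy as np
import pytest

from isisblasso.io import GenotypeData


@pytest.fixture
def rng():
    return np.random.default_rng(20170131)


@pytest.fixture
def small_genotypes(rng) -> GenotypeData:
    """40 lines x 30 polymorphic 0/1 SNPs on two chromosomes."""
    mat = (rng.random((40, 30)) < 0.4).astype(float)
    # guarantee polymorphism
    mat[0, :] = 0.0
    mat[1, :] = 1.0
    return GenotypeData(
        matrix=mat,
        snp_ids=np.array([f"s{j}" for j in range(30)], dtype=object),
        chromosome=np.array(["1"] * 15 + ["2"] * 15, dtype=object),
        position_bp=np.arange(1, 31) * 1000,
    )
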