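import numpy as np
import pytest

from hbmix import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def case1_small():
    """One small Case 1 study shared by read-only tests."""
    cfg = SimConfig(n_samples=300, n_snps=500, mixture_p=0.02, slab_var=0.1,
                    target_pve=0.5, seed=11)
    g, std, y, truth = simulate_dataset(cfg)
    return g, std, y, truth


@pytest.fixture()
def tiny_genotypes():
    """Hand-written 4-sample x 3-SNP matrix with one missing call."""
    from hbmix import GenotypeMatrix
    counts = np.array([[0.0, 1.0, 2.0],
                       [1.0, 0.0, 2.0],
                       [2.0, np.nan, 1.0],
                       [1.0, 1.0, 0.0]])
    return GenotypeMatrix(samples=["a", "b", "c", "d"],
                          snps=["rs1", "rs2", "rs3"], counts=counts)
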