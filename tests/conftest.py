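import numpy as np
import pandas as pd
import pytest

from fertqtl import lmm, simulate
from fertqtl.io import GenotypeMatrix


@pytest.fixture(scope="session")
def small_cfg():
    return simulate.SimConfig(
        n_samples=300, n_chromosomes=2, variants_per_chrom=400,
        chrom_length_bp=20_000_000, n_genes=40, n_expr_samples=300,
        n_trans_egenes=3, seed=11,
    )


@pytest.fixture(scope="session")
def small_geno(small_cfg):
    return simulate.simulate_genotypes(small_cfg)


@pytest.fixture(scope="session")
def small_traits(small_cfg, small_geno):
    return simulate.simulate_traits(small_geno, small_cfg)


@pytest.fixture(scope="session")
def small_grm(small_geno):
    return lmm.compute_grm(small_geno, maf_min=0.01)


def make_geno(dosage, chrom="1", start_pos=100, spacing=1000, samples=None):
    """Hand-built GenotypeMatrix from a samples x variants dosage array."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    samples = samples or [f"s{i}" for i in range(n)]
    variants = pd.DataFrame({
        "chrom": chrom,
        "pos": start_pos + spacing * np.arange(m),
        "id": [f"{chrom}:{start_pos + spacing * j}" for j in range(m)],
        "ref": "A", "alt": "G",
        "maf": [min(p, 1 - p) for p in dosage.mean(axis=0) / 2],
        "accuracy": 0.99,
    })
    return GenotypeMatrix(samples, variants, dosage)
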