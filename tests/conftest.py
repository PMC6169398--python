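import numpy as np
import pytest

from clinalscan.genotype_io import GenotypeMatrix, VariantInfo


def make_gm(dosages, positions=None, chrom="Chr01", sample_prefix="s"):
    """Build a GenotypeMatrix from a 2-D array of dosages."""
    d = np.asarray(dosages, dtype=np.int16)
    n, m = d.shape
    if positions is None:
        positions = list(range(1, m + 1))
    if isinstance(chrom, str):
        chrom = [chrom] * m
    variants = [VariantInfo(c, int(p), "A", "T", f"v{j}")
                for j, (c, p) in enumerate(zip(chrom, positions))]
    return GenotypeMatrix(d, [f"{sample_prefix}{i}" for i in range(n)],
                          variants)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_gm(rng):
    """A 40-sample x 100-variant unstructured panel without missing data."""
    p = rng.uniform(0.05, 0.95, 100)
    return make_gm(rng.binomial(2, p, size=(40, 100)),
                   positions=sorted(rng.choice(10**6, 100, replace=False)))


@pytest.fixture
def small_landscape():
    from clinalscan import LandscapeConfig, simulate_landscape

    cfg = LandscapeConfig(n_samples=90, n_snps=600, n_clinal_loci=60, seed=7)
    return simulate_landscape(cfg)
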