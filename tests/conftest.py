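import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import genewise as gw

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_dataset(dosages, phenotype, chrom="chr1", spacing=1000, start=100):
    """Build a GenotypeDataset from a raw dosage matrix (samples x snps)."""
    dosages = np.asarray(dosages, dtype=float)
    n_samples, n_snps = dosages.shape
    snps = [
        gw.SnpRecord(snp_id=f"snp{j:03d}", chrom=chrom, pos=start + j * spacing)
        for j in range(n_snps)
    ]
    return gw.GenotypeDataset(
        snps=snps,
        samples=[f"S{i:03d}" for i in range(n_samples)],
        dosages=dosages,
        phenotype=np.asarray(phenotype, dtype=np.int8),
    )


def random_dataset(rng, n_cases=50, n_controls=50, n_snps=20, maf_low=0.1, maf_high=0.5):
    """Null dataset: genotypes independent of the phenotype."""
    n = n_cases + n_controls
    freqs = rng.uniform(maf_low, maf_high, size=n_snps)
    dosages = rng.binomial(2, freqs, size=(n, n_snps)).astype(float)
    phenotype = np.concatenate(
        [np.ones(n_cases, dtype=np.int8), np.zeros(n_controls, dtype=np.int8)]
    )
    return make_dataset(dosages, phenotype)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_null_dataset(rng):
    return random_dataset(rng, n_cases=40, n_controls=40, n_snps=12)
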