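import numpy as np
import pandas as pd
import pytest

import liabscreen as ls
from liabscreen.data import make_sample_table, make_snp_table


def random_dataset(n, m, seed=0, missing_frac=0.0):
    """Small random hard-call dataset for round-trip and estimator tests."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.5, size=m)
    d = rng.binomial(2, p, size=(n, m)).astype(np.float32)
    if missing_frac:
        mask = rng.random((n, m)) < missing_frac
        d[mask] = np.nan
    samples = make_sample_table(
        [f"s{i:04d}" for i in range(n)],
        sex=list(rng.choice(["male", "female"], size=n)),
        birth_decade=list(rng.choice([1940, 1950, 1960], size=n)),
        age=list(rng.integers(30, 80, size=n).astype(float)),
    )
    snps = make_snp_table(
        [f"rs{j:04d}" for j in range(m)],
        chrom=[str(rng.integers(1, 23)) for _ in range(m)],
        pos=sorted(rng.choice(np.arange(1, 10_000_000), size=m, replace=False)),
        a1="A",
        a2="C",
    )
    return ls.GenotypeDataset(samples, snps, d)


@pytest.fixture(scope="session")
def structured_sim():
    """Mid-size simulated cohort with an HLA block, shared across tests."""
    return ls.simulate_genotypes(600, 2000, seed=42)


@pytest.fixture(scope="session")
def structured_grm(structured_sim):
    return ls.compute_grm(structured_sim)
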