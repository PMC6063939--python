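"""Shared fixtures: small synthetic cohorts and hand-built genotype matrices."""

import numpy as np
import pytest

import phenoscore as ps
from phenoscore.containers import GenotypeMatrix


def make_gm(dosages, **kwargs) -> GenotypeMatrix:
    """GenotypeMatrix from a plain dosage array with auto metadata."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    defaults = dict(
        variant_ids=[f"v{j}" for j in range(m)],
        chrom=np.ones(m, dtype=int),
        pos=np.arange(1, m + 1),
        allele1=["A"] * m,
        allele2=["B"] * m,
        sample_ids=[f"s{i}" for i in range(n)],
    )
    defaults.update(kwargs)
    return GenotypeMatrix(dosages=dosages, **defaults)


@pytest.fixture(scope="session")
def tiny_cohort():
    """300 samples x 120 variants; big enough to exercise every stage."""
    cfg = ps.SimConfig(
        n_samples=300,
        n_variants=120,
        n_causal=15,
        h2_liability=0.6,
        prevalence=0.15,
        seed=42,
    )
    return cfg, ps.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def medium_cohort():
    """2000 x 600 cohort reused by the heavier CV tests."""
    cfg = ps.SimConfig(
        n_samples=2000,
        n_variants=600,
        n_causal=30,
        h2_liability=0.5,
        prevalence=0.10,
        seed=7,
    )
    return cfg, ps.simulate_cohort(cfg)
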