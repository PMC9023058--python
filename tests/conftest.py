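"""Shared fixtures: small seeded datasets reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from rejuvkit import synthetic as syn


@pytest.fixture(scope="session")
def small_cohort():
    """A small noiseless methylation cohort with planted aging CpGs."""
    spec = syn.CohortSpec(n_samples=60, n_cpgs=200, n_aging_cpgs=50,
                          noise_sd=0.0, seed=11)
    betas, samples, gt = syn.simulate_aging_methylation(spec)
    return spec, betas, samples, gt


@pytest.fixture(scope="session")
def small_expression():
    """A small expression cohort with planted aging genes."""
    spec = syn.ExpressionSpec(n_genes=150, n_aging_genes=60, noise_sd=0.1,
                              seed=12)
    expr, samples, gt = syn.simulate_aging_expression(spec)
    return spec, expr, samples, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def tiny_tss():
    return pd.DataFrame(
        {"chrom": ["chr1", "chr1", "chr2"], "tss": [1_000, 50_000, 10_000]},
        index=pd.Index(["geneA", "geneB", "geneC"], name="gene_id"),
    )
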