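"""Shared fixtures: synthetic cohorts and reusable MCMC fits.

The expensive fits are session-scoped so independent tests share them;
everything is seeded, so the suite is fully deterministic.
"""

import numpy as np
import pandas as pd
import pytest

import acenodose as ad


@pytest.fixture(scope="session")
def default_cohort():
    cohort, truth = ad.simulate_cohort(ad.SimulationConfig(seed=1))
    return cohort, truth


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (4 genes) for fast MCMC-backed tests."""
    cfg = ad.SimulationConfig(seed=11, n_genes=4)
    cohort, truth = ad.simulate_cohort(cfg)
    return cohort, truth


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    cohort, _ = small_cohort
    design = ad.default_design(cohort)
    settings = ad.McmcSettings(n_chains=3, n_iterations=6000, n_burnin=1000,
                               thinning=5, seed=11)
    samples = ad.fit_mcmc(design, cohort.dose.to_numpy(), ad.ModelSpec(), settings)
    return cohort, design, samples


def make_cohort(genotypes, variant_ids=None, genes=None, doses=None, covariates=None):
    """Hand-built cohort from a genotype matrix (helper for crafted fixtures)."""
    genotypes = np.asarray(genotypes, dtype=float)
    n, p = genotypes.shape
    samples = [f"S{i}" for i in range(n)]
    if variant_ids is None:
        variant_ids = [f"rs{j + 1}" for j in range(p)]
    if genes is None:
        genes = ["G1"] * p
    variants = [
        ad.VariantRecord(variant_id=vid, chrom="chr1", pos=100 * (j + 1),
                         ref_allele="A", alt_allele="G", gene=genes[j])
        for j, vid in enumerate(variant_ids)
    ]
    cov = None
    if covariates is not None:
        cov = pd.DataFrame(covariates, index=samples)
    dose = None
    if doses is not None:
        dose = pd.Series(np.asarray(doses, dtype=float), index=samples)
    return ad.Cohort(samples=samples, genotypes=genotypes, variants=variants,
                     covariates=cov, dose=dose)
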