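"""Fit the spike-and-slab Bayesian gamma GLM to a synthetic cohort.

Builds the dosing design (genotype-class dummies, within-gene interaction
terms, standardized clinical covariates), runs the desk-scale MCMC protocol
(5 chains x 11,000 iterations, 1,000 burn-in), checks Gelman-Rubin
convergence and prints the terms with the highest posterior inclusion
probability.  Takes ~20 s.
"""

import numpy as np

import acenodose as ad

cohort, truth = ad.simulate_cohort(ad.SimulationConfig(seed=1))
design = ad.default_design(cohort)
print(f"design: {design.X_cov.shape[1]} covariates, "
      f"{design.n_term_columns} genotype columns in {len(design.groups)} "
      f"indicator groups")

samples = ad.fit_mcmc(design, cohort.dose.to_numpy(), ad.ModelSpec(),
                      ad.McmcSettings.scaled_down(seed=1))
finite = {k: v for k, v in samples.rhat.items() if np.isfinite(v)}
print(f"converged: {samples.converged} (max R-hat = {max(finite.values()):.3f})")

report = ad.summarize_posterior(samples)
print("\ncovariates and top genetic terms (posterior mean, 95% HDI, PIP):")
cols = ["term", "mean", "hdi_low", "hdi_high", "pip", "bayes_factor_report"]
print(report.head(10)[cols].round(3).to_string(index=False))
# A high-PIP heterozygote term at CYP2D8P POS42547668 should surface: the
# generator gave it a +0.899 log-dose effect, a near-doubling of dose.
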