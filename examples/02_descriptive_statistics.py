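"""Descriptive pharmacogenetics on a synthetic cohort.

Computes per-variant allele frequencies with Hardy-Weinberg exact tests
(BH-FDR adjusted), per-individual het/hom tallies, the per-gene
novel/known and impact table, and an FST differentiation screen against a
mock reference population.
"""

import numpy as np
import pandas as pd

import acenodose as ad

cohort, _ = ad.simulate_cohort(ad.SimulationConfig(seed=1))

summary = ad.summarize_variants(cohort)
n_hwe_fail = int((summary["hwe_q"] < 0.05).sum())
print(f"{len(summary)} variants; {n_hwe_fail} fail Hardy-Weinberg at FDR q < 0.05")

tallies = ad.per_individual_counts(cohort)
print(f"per individual (mean): {tallies['n_variant_sites'].mean():.0f} variant sites, "
      f"{tallies['n_het'].mean():.0f} heterozygous, "
      f"{tallies['n_hom_alt'].mean():.0f} homozygous-alt")

novelty = ad.novelty_impact_summary(cohort.variants, summary["maf"])
top = novelty.sort_values("novel_to_known_ratio", ascending=False).head(3)
print("highest novel-to-known ratios:")
print(top[["n_known", "n_novel", "novel_to_known_ratio"]].round(2).to_string())

# mock reference: same frequencies except 8 variants pushed to fixation,
# as a stand-in for a 1000G-style population panel
rng = np.random.default_rng(0)
ids = list(summary.index)
freqs = summary["alt_freq"].to_numpy().copy()
forced = rng.choice(len(ids), size=8, replace=False)
freqs[forced] = np.where(freqs[forced] < 0.5, 1.0, 0.0)
reference = ad.ReferenceFrequencyTable(pd.DataFrame({
    "population": "MOCK", "variant_id": ids,
    "alt_freq": freqs, "n_chromosomes": 200}))
screen = ad.differentiation_screen(cohort, reference)
above = screen["MOCK"]["above_threshold"].sum()
print(f"FST screen vs MOCK: {above} variants above 0.25 "
      f"(the {len(forced)} forced fixations dominate)")
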