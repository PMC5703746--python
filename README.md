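# acenodose

Bayesian pharmacogenetic dose modelling for acenocoumarol.

Acenocoumarol (4-nitrowarfarin) is the coumarin anticoagulant of choice in
much of Europe and Latin America. Its safe dose varies several-fold between
patients, and a large part of that variation is genetic — most prominently
variants in *VKORC1*, the drug's molecular target. `acenodose` is a library
for the statistical side of a targeted-resequencing dose study: it takes a
genotyped cohort (VCF + clinical table), produces the descriptive
population-genetic layer, fits a Bayesian variable-selection dose model
over thousands of candidate SNPs and within-gene SNP interactions, selects
a final model by Bayes factors and DIC, and evaluates published dosing
equations on new patients. A synthetic-cohort generator with known truth
makes every stage testable without access to patient data.

## The model

Weekly dose *y<sub>i</sub>* is gamma-distributed with shape τ and mean
μ<sub>i</sub> given by a log link:

```
log E[y|θ] = c + Σᵢ αᵢ xᵢ  +  Σⱼ Iⱼ (β₁ⱼ v₁ⱼ + β₂ⱼ v₂ⱼ)
           + Σ_g Σ_{j<k} I_{jk} ( β¹¹ v₁ⱼv₁ₖ + β¹² v₁ⱼv₂ₖ + β²¹ v₂ⱼv₁ₖ + β²² v₂ⱼv₂ₖ )
```

where *x* are standardized clinical covariates (age, sex, weight, height),
*v₁ⱼ*/*v₂ⱼ* are heterozygote / homozygote-alt indicators of SNP *j*, and
the interaction sum runs over SNP pairs within the same gene *g*. Each SNP
and each pair carries a Bernoulli(π) inclusion indicator *I* (spike), its
effects a Laplace(0, τ_β) slab, with π ~ U(a, b), c and α normal, and
τ ~ Gamma(λ, κ). The sampler is the package's own Metropolis-within-Gibbs
kernel (numba-compiled) with reversible add/delete/swap jumps over the
indicator space; convergence is checked with the Gelman-Rubin statistic
(R̂ < 1.2) over five chains. Candidate terms are filtered to alt-allele
frequency ∈ (0.05, 0.95) for main effects and (0.10, 0.90) for
interactions. Model selection conditions inclusion Bayes factors along a
decision tree with cutoff c_j = 3 + m_j (m_j = terms conditioned absent on
the path) and ranks candidate models by DIC.

The descriptive layer reproduces the standard resequencing statistics:
allele frequencies, exact Hardy-Weinberg tests with Benjamini-Hochberg FDR,
per-individual heterozygous/homozygous tallies, per-gene novel/known and
impact-class summaries, composite LD r, and FST differentiation
(Weir-Cockerham or Wright) against any user-supplied reference frequency
table.

## Worked example

```python
import acenodose as ad

cohort, truth = ad.simulate_cohort(ad.SimulationConfig(seed=1))
design = ad.default_design(cohort)
samples = ad.fit_mcmc(design, cohort.dose.to_numpy(), ad.ModelSpec(),
                      ad.McmcSettings.scaled_down(seed=1))
print(ad.summarize_posterior(samples).head(7))
```

prints (about 20 s; `examples/03_fit_dose_model.py`):

```
           term   mean  hdi_low  hdi_high   pip bayes_factor_report
      intercept  0.865    0.570     1.148 1.000                >900
            age -0.097   -0.195     0.002 1.000                >900
            sex  0.086   -0.103     0.274 1.000                >900
         weight  0.014   -0.082     0.115 1.000                >900
         height  0.188    0.095     0.283 1.000                >900
POS42547668:hom -0.131   -0.609     0.378 0.968              576.20
POS42547668:het  0.967    0.748     1.181 0.968              576.20
```

The generator planted a +0.899 log-dose effect on the heterozygous
CYP2D8P POS42547668 genotype; the fit recovers it (posterior mean 0.97,
95% HDI 0.75–1.18) with posterior inclusion probability 0.97. The
covariate rows are on the standardized scale; `mean_natural` in the full
report divides by the stored covariate SD.

Evaluating the published interaction dosing equation
(`examples/05_dose_prediction.py`):

```
model1_interactions:
  wild-type male           ln dose = +0.8960 -> 2.45 model units
  VKORC1 het diplotype     ln dose = +0.6830 -> 1.98 model units
  VKORC1 hom diplotype     ln dose = +0.1770 -> 1.19 model units
  CYP2D8P het carrier      ln dose = +1.7950 -> 6.02 model units
```

The homozygous VKORC1 diplotype halves the predicted dose
(exp(−0.719) ≈ 0.49); the CYP2D8P variant raises it 2.5-fold.

Each script in `examples/` is a short narrative of one capability:
simulation, descriptives, model fitting, selection, and dose prediction.
A thin CLI mirrors them: `acenodose {simulate,describe,fit,select,predict}`.

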