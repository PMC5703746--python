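# Methods

## The dose model

Dose is modelled as gamma with a logarithmic link: y_i ~ Gamma(shape τ,
rate τ/μ_i), so E[y_i] = μ_i = exp(η_i) and the shape controls relative
noise — Var(log y | μ) = ψ′(τ) (trigamma). Describing the gamma dispersion
as a "variance" parameter is ambiguous under a log link; this package fixes
the convention τ = shape and uses the mean-rate identity rate = τ/μ
throughout (generator, likelihood, DIC).

The linear predictor has three blocks:

* **Covariates** — age (y), sex, weight (kg), height (m), standardized to
  mean zero and unit sample variance (divisor n−1). Sex is kept as a 0/1
  male indicator by default (the published equations carry an "(if male)"
  clause, which implies an unstandardized binary term); a config switch
  standardizes it. BMI can replace weight/height via configuration. The
  standardization constants are stored on the design so standardized
  coefficients map back to natural units (coef/SD); this reconciles
  Table-style standardized effects (−0.102 per SD of age) with
  equation-style natural ones (−0.0071 per year, given an age SD ≈ 14 y).
* **Main effects** — per SNP two dummies: heterozygote and homozygote-alt
  indicators (genotype 0 → (0,0), 1 → (1,0), 2 → (0,1)). Candidate SNPs
  must have alt-allele frequency strictly inside (0.05, 0.95). The filter
  is on alt-allele frequency, not folded MAF; both bounds are strict and
  configurable, and every exclusion is logged with its reason.
* **Within-gene interactions** — for every unordered SNP pair within one
  gene whose members have frequency strictly inside (0.10, 0.90), the four
  products of genotype dummies. One inclusion indicator covers a SNP's two
  columns, and one covers a pair's four columns. Interaction indicators
  are independent of their parents' (no hierarchy constraint); the
  alternative — only proposing a pair when a parent main effect is in —
  would shrink the search space but changes the model, so it is not done.

Missing genotypes: variants with missingness above 10% (configurable) are
dropped before modelling; remaining missing calls are mean-imputed on the
dummy scale (logged). Constant columns are dropped with a warning.

## Priors

The inference protocol (five chains of 110,000 iterations, 10,000 burn-in,
random initial values, R̂ < 1.2) fixes no hyperparameter values, so these
are package defaults, chosen vague-but-proper and all configurable:

| parameter | prior | default | rationale |
|---|---|---|---|
| τ (gamma shape) | Gamma(λ, κ) | λ = κ = 0.01 | vague on dispersion |
| c (intercept) | Normal(0, τ_μ²) | τ_μ² = 100 | weak |
| α (covariates) | Normal(0, τ_α²) | τ_α² = 100 | weak |
| β (effects) | Laplace(0, τ_β) | τ_β = 1 | regularizing slab on log-dose scale |
| I (indicators) | Bernoulli(π) | — | spike: exact zero when excluded |
| π | Uniform(a, b) | (0.001, 0.1) | sparsity over thousands of candidates |

The Laplace slab's second argument is read as a scale parameter. The prior
inclusion probability used for Bayes factors is the prior-predictive mean
E[π] = (a+b)/2.

## Sampler

A Metropolis-within-Gibbs kernel (numba-compiled, `_sampler.py`), one call
per chain:

* random-walk updates for c, each α, each included β (Laplace prior), and
  log τ; a random-walk update for π inside [a, b] against its binomial
  conditional. Step sizes adapt toward 40% acceptance in batches of 100
  iterations **during burn-in only**, so retained draws target the exact
  posterior.
* **add/delete** moves per indicator group: entering effects are proposed
  from a 50/50 mixture of the slab prior and a normal centred on the
  column's univariate least-squares estimate (computed once from
  covariate-adjusted log dose); the acceptance ratio carries the exact
  proposal-density correction, so this improves mixing without touching
  the target.
* **swap** moves between an interaction group and the main-effect groups
  of its member SNPs. These near-collinear explanations form posterior
  modes that one-at-a-time flips traverse too slowly; a joint
  delete-one/add-one step lets chains hop between them.
* add/delete/swap jumps are **intercept-centred**: the intercept absorbs
  the entering/leaving group's mean contribution (a shear map with unit
  Jacobian). Without this, high-frequency columns and the intercept form
  a level ridge on which chains can stall for an entire run.
* the linear predictor and the weights y·exp(−η) are maintained
  incrementally through sparse column structures and refreshed exactly
  every 2,000 iterations against drift.

Correctness is checked two ways: a likelihood-off run must reproduce every
prior marginal (KS < 0.05 against Normal/Laplace/Uniform/Gamma; mean
inclusion equal to E[π]), and the Gelman-Rubin implementation is tested to
1e−10 against an independent textbook formulation. R̂ is computed for the
intercept, covariates, log τ, π, and the effects of terms with PIP ≥ 0.9;
marginal draws of lower-PIP effects are spike/slab mixtures for which a
variance-ratio diagnostic is not meaningful. Chains are seeded
deterministically from the user seed; identical settings give bit-identical
draws.

Desk-scale default: `McmcSettings.scaled_down()` = 5 chains × 11,000
iterations, 1,000 burn-in, thinning 10 (~20 s on one CPU for the default
cohort's ~220 groups). The full 5 × 110,000 protocol is one argument away
and takes ~10×.

## Selection

The inclusion Bayes factor of a term is Savage-Dickey-style for its
indicator: posterior odds of I = 1 within the subset of draws satisfying
the conditioning states on the path, divided by the prior odds from E[π].
Reported values are capped at ">900"; raw values are kept. Conditioning
subsets below 200 draws raise an error (remedy: longer chains) rather than
returning noise. Tree growth is greedy in PIP order; each branch retains
the first candidate whose conditioned BF clears c_j = 3 + m_j, and both
the included (solid) and excluded (dashed) child branches are explored. A
`never_condition` list exempts named terms from branching. Tree
construction order is a package decision — the published figure shows a
result, not an algorithm.

DIC = D̄ + p_D with D = −2 log L and p_D = D̄ − D(posterior means). DIC
comparisons between *fixed* term sets refit the subset design with the
inclusion prior pinned near 1 (π ~ U(0.98, 0.999)), since the DIC of a
spike-and-slab fit is not attributable to any single submodel.

Variance explained defaults to 100 × the squared Pearson correlation
between observed and predicted log dose; a deviance-based pseudo-R² is
available and reported side by side. The predicted-vs-observed comparison
is a paired two-sided test among INR-stable samples (Wilcoxon signed-rank
default, paired t-test option). For raw-dose comparisons under a gamma
model the t-test is the sharper instrument — E[pred − obs] = 0 exactly,
whereas the signed-rank statistic responds to the benign mean-median
offset of the gamma distribution.

## Synthetic cohorts

The generator emulates the study conditions the analysis assumes:

* n = 100 patients; 20 genes with 3–7 SNPs each (~100 SNPs, ≤ 200
  main-effect columns); alt frequencies from MAF ~ U(0.02, 0.5) with
  random allele orientation; ~28% of variants novel (no rs identifier).
* genotypes are Binomial(2, p) per SNP — exact Hardy-Weinberg — except
  the linked VKORC1 pair rs8050894/rs9934438, generated by sampling two
  haplotypes per individual from explicit 4-haplotype frequencies chosen
  to hit the target correlation (r = 0.492, the value reported for this
  pair) while keeping each margin Hardy-Weinberg. Infeasible (MAF, r)
  combinations raise an error stating the attainable bound. Pair MAFs
  default to 0.45, the neighbourhood of these variants' frequencies in
  Mexican-Mestizo reference panels. The generator targets r, not r²
  (the source convention is ambiguous; composite genotype r is also what
  the LD module reports, phase being unobserved).
* covariates are uniform on demographic ranges (age 17–85 y, weight
  37–121 kg, height 1.4–1.8 m), sex Bernoulli(0.5).
* doses come from the gamma model itself, with true effects defaulting to
  the published Model-1 magnitudes: diplotype effects −0.213 (het/het)
  and −0.719 (hom/hom) on the VKORC1-like pair, +0.899 on a heterozygous
  CYP2D8P-like novel variant, +0.203 on heterozygous SULT1A1 rs11648192,
  and standardized covariate effects (−0.102, +0.047, +0.110, −0.124).
  gamma_shape defaults to 5.5, chosen so ψ′(τ) matches the residual
  log-dose variance implied by a generative log-scale R² ≈ 0.56 — the
  magnitude of the published 55.9% variance explained.
  `shape_for_target_r2` inverts the trigamma for exact calibration.

All randomness flows through numpy's PCG64 with fixed per-operation
streams: cohorts are bit-identical across runs and platforms.

What the generator does **not** emulate: linkage beyond the one declared
pair, admixture and population structure, genotyping error, sequencing
depth, covariate correlations (e.g. weight with sex), or dose titration
dynamics. Passing recovery tests therefore show the estimator works when
its assumptions hold; they do not certify performance on real cohorts.

## Recovery at these conditions — a known limit

With n = 100, ~220 candidate groups and noise calibrated to R² ≈ 0.56, the
VKORC1-like *pair* carries a realized log-likelihood gain of only ~3–11
nats (the hom-hom diplotype count fluctuates binomially between ~4 and 12
carriers), while the four-parameter slab's Occam penalty is ~5–8 nats and
the posterior-adapted π (~0.01) contributes prior log-odds ≈ −4.6. A
Laplace approximation of the exact inclusion posterior gives pair PIP
between ~0.02 and ~0.5 depending on the seed — so no sampler can push the
pair's PIP above 0.8 consistently at this design. The recovery suite
reflects this honestly: the strong single-SNP effect (+0.899) is recovered
with PIP ≈ 1 and calibrated HDIs, the calibrated variance-explained check
recovers the generative R², and the pair-PIP experiment reports its
failure rather than being tuned until it passes. At n ≈ 200+, or with
commoner diplotypes, the pair is recovered as well.

## Dose calculator

The two published equations are hard-coded as immutable clause lists
(conditions on genotype classes at VKORC1 rs8050894/rs9934438, CYP2D8P
POS42547668, SULT1A1 rs11648192) plus natural-unit covariate coefficients;
`ln_dose` is a pure sum and every printed coefficient is asserted
bit-exactly by clause isolation in the tests. Heterozygote clauses like
"C/G" are unordered; homozygous reference is the implicit baseline.
Missing genotypes are a hard error unless `assume_reference` is set. Where
the printed equation and the summary-table value of the same coefficient
disagree (Model 2's G/A term: −0.239 vs −0.235), the equation is taken as
authoritative. Output is labelled "model units": the source reports
weekly doses in its demographics but daily doses in its worked
predictions, and exp of the typical ln-dose (~0.9) sits in the mg/day
range; a config override attaches a concrete unit. Fitted models from the
selection module evaluate through the term registry and stored
standardization constants, and agree with the posterior-mean MCMC
predictor to machine precision on the fitted cohort.

## Test-scale choices

The suite runs MCMC-backed checks at reduced sizes chosen for a
single-CPU run: recovery and selection experiments use 2–3 chains of
4,000–6,000 iterations on cohorts of 3–6 genes; the convergence check and
the acceptance script use the full default cohort at the desk-scale
protocol. Exhaustive oracles (Hardy-Weinberg enumeration over all tables
with n ≤ 50, brute-force BH, textbook Gelman-Rubin) run at full fidelity.
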