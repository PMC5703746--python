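"""Synthetic cohort generator.

Emulates the statistical structure the dose analysis assumes: ~100
individuals, biallelic SNPs grouped into genes with Hardy-Weinberg
genotypes at sampled MAFs, one linked VKORC1-like pair generated from
explicit two-locus haplotype frequencies tuned to a target correlation, and
weekly doses drawn from a gamma model with logarithmic link whose true
effect sizes default to the printed dose-model magnitudes (diplotype
effects -0.213/-0.719, heterozygote effects +0.899 and +0.203).

All randomness flows through numpy's PCG64 ``default_rng`` seeded from the
config, with a fixed stream per operation, so cohorts are bit-identical
across runs and platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special

from .cohort import Cohort, DoseUnits, Impact, VariantRecord

# sub-stream tags so the three simulate_* operations are independently
# reproducible from one seed
_GENO_STREAM = 1
_COV_STREAM = 2
_DOSE_STREAM = 3


@dataclass(frozen=True)
class LdPair:
    """A pair of linked SNPs generated from 4-haplotype frequencies."""

    gene: str
    variant_id1: str
    variant_id2: str
    maf1: float
    maf2: float
    target_r: float


@dataclass(frozen=True)
class GenotypeEffect:
    """Additive log-dose effect of one genotype class (1 = het, 2 = hom-alt)."""

    variant_id: str
    genotype_class: int
    effect: float


@dataclass(frozen=True)
class PairEffect:
    """Log-dose effect of a joint genotype (diplotype) at two linked SNPs."""

    variant_id1: str
    variant_id2: str
    class1: int
    class2: int
    effect: float


def _default_ld_pairs() -> list[LdPair]:
    # VKORC1 rs8050894/rs9934438 sit near 0.45 minor-allele frequency in
    # Mexican-Mestizo reference panels; the pair correlation targets the
    # cohort-reported genotype r of 0.492
    return [LdPair("VKORC1", "rs8050894", "rs9934438", 0.45, 0.45, 0.492)]


def _default_anchors() -> list[tuple[str, str, float]]:
    return [("CYP2D8P", "POS42547668", 0.15), ("SULT1A1", "rs11648192", 0.30)]


def _default_effects() -> list[GenotypeEffect | PairEffect]:
    return [
        PairEffect("rs8050894", "rs9934438", 1, 1, -0.213),
        PairEffect("rs8050894", "rs9934438", 2, 2, -0.719),
        GenotypeEffect("POS42547668", 1, 0.899),
        GenotypeEffect("rs11648192", 1, 0.203),
    ]


def _default_covariate_effects() -> dict[str, float]:
    # standardized-scale covariate effects; sex applies to a 0/1 male indicator
    return {"age": -0.102, "weight": 0.047, "height": 0.110, "sex": -0.124}


def _default_covariate_ranges() -> dict[str, tuple[float, float]]:
    return {"age": (17.0, 85.0), "weight": (37.0, 121.0), "height": (1.4, 1.8)}


@dataclass
class SimulationConfig:
    n_samples: int = 100
    n_genes: int = 20
    snps_per_gene: tuple[int, int] = (3, 7)
    maf_range: tuple[float, float] = (0.02, 0.5)
    novel_fraction: float = 0.28
    ld_pairs: list[LdPair] = field(default_factory=_default_ld_pairs)
    anchor_variants: list[tuple[str, str, float]] = field(default_factory=_default_anchors)
    true_effects: list[GenotypeEffect | PairEffect] = field(default_factory=_default_effects)
    covariate_effects: dict[str, float] = field(default_factory=_default_covariate_effects)
    covariate_ranges: dict[str, tuple[float, float]] = field(default_factory=_default_covariate_ranges)
    intercept: float = 0.884
    gamma_shape: float = 5.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < low <= high <= 0.5, got {self.maf_range}")
        for pair in self.ld_pairs:
            if abs(pair.target_r) > 1:
                raise ValueError(f"|target_r| > 1 for pair {pair.variant_id1}/{pair.variant_id2}")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")


def haplotype_frequencies(p1: float, p2: float, r: float) -> np.ndarray:
    """4-haplotype frequencies (AB, Ab, aB, ab; A/B = alt) with correlation r.

    Raises if r is infeasible for the given allele frequencies, stating the
    attainable bound.
    """
    q1, q2 = 1 - p1, 1 - p2
    denom = np.sqrt(p1 * q1 * p2 * q2)
    d = r * denom
    d_min = max(-p1 * p2, -q1 * q2)
    d_max = min(p1 * q2, q1 * p2)
    if not (d_min - 1e-12 <= d <= d_max + 1e-12):
        r_lo, r_hi = d_min / denom, d_max / denom
        raise ValueError(
            f"target r = {r} infeasible at alt freqs ({p1}, {p2}); "
            f"attainable r in [{r_lo:.4f}, {r_hi:.4f}]"
        )
    h = np.array([p1 * p2 + d, p1 * q2 - d, q1 * p2 - d, q1 * q2 + d])
    return np.clip(h, 0.0, 1.0) / np.clip(h, 0.0, 1.0).sum()


def _gene_names(config: SimulationConfig) -> list[str]:
    special = [p.gene for p in config.ld_pairs]
    special += [g for g, _, _ in config.anchor_variants if g not in special]
    extra = [f"GENE{i:02d}" for i in range(1, config.n_genes + 1)]
    names = special + [g for g in extra if g not in special]
    return names[: max(config.n_genes, len(special))]


def simulate_genotypes(config: SimulationConfig) -> tuple[np.ndarray, list[VariantRecord]]:
    """Draw the genotype matrix and variant annotations.

    Non-LD SNPs are Binomial(2, alt_freq) per sample — exact Hardy-Weinberg
    at their allele frequency.  LD pairs are built by sampling two haplotypes
    per individual from the 4-haplotype distribution, which keeps each margin
    Hardy-Weinberg while hitting the target correlation.
    """
    rng = np.random.default_rng([_GENO_STREAM, config.seed])
    n = config.n_samples
    genes = _gene_names(config)
    pair_by_gene = {p.gene: p for p in config.ld_pairs}
    anchors_by_gene: dict[str, list[tuple[str, float]]] = {}
    for g, vid, maf in config.anchor_variants:
        anchors_by_gene.setdefault(g, []).append((vid, maf))

    columns: list[np.ndarray] = []
    records: list[VariantRecord] = []
    pos = 1000
    rs_counter = 1_000_000
    for gi, gene in enumerate(genes):
        chrom = f"chr{gi % 22 + 1}"
        n_snps = int(rng.integers(config.snps_per_gene[0], config.snps_per_gene[1] + 1))
        placed = 0
        if gene in pair_by_gene:
            pair = pair_by_gene[gene]
            h = haplotype_frequencies(pair.maf1, pair.maf2, pair.target_r)
            hap1 = rng.choice(4, size=n, p=h)
            hap2 = rng.choice(4, size=n, p=h)
            # haplotype codes: 0=AB, 1=Ab, 2=aB, 3=ab (A/B carry the alt allele)
            g1 = (np.isin(hap1, (0, 1)).astype(float) + np.isin(hap2, (0, 1)))
            g2 = (np.isin(hap1, (0, 2)).astype(float) + np.isin(hap2, (0, 2)))
            for vid, col in ((pair.variant_id1, g1), (pair.variant_id2, g2)):
                pos += int(rng.integers(200, 2000))
                records.append(_make_record(vid, chrom, pos, gene, rng))
                columns.append(col.astype(float))
                placed += 1
        for vid, maf in anchors_by_gene.get(gene, []):
            pos += int(rng.integers(200, 2000))
            if vid.startswith("POS"):
                anchor_pos = int(vid[3:])
                records.append(_make_record(vid, chrom, anchor_pos, gene, rng))
            else:
                records.append(_make_record(vid, chrom, pos, gene, rng))
            columns.append(rng.binomial(2, maf, size=n).astype(float))
            placed += 1
        for _ in range(max(n_snps - placed, 1) if placed == 0 else max(n_snps - placed, 0)):
            pos += int(rng.integers(200, 2000))
            maf = float(rng.uniform(*config.maf_range))
            alt_freq = maf if rng.random() < 0.5 else 1 - maf
            if rng.random() < config.novel_fraction:
                vid = VariantRecord.novel_id(pos)
            else:
                rs_counter += int(rng.integers(1, 5000))
                vid = f"rs{rs_counter}"
            records.append(_make_record(vid, chrom, pos, gene, rng))
            columns.append(rng.binomial(2, alt_freq, size=n).astype(float))
    genotypes = np.column_stack(columns)
    return genotypes, records


_BASES = np.array(list("ACGT"))


def _make_record(vid: str, chrom: str, pos: int, gene: str, rng: np.random.Generator) -> VariantRecord:
    ref, alt = rng.choice(4, size=2, replace=False)
    impact = (Impact.LOW, Impact.MODIFIER, Impact.MODERATE, Impact.HIGH)[
        int(rng.choice(4, p=[0.35, 0.45, 0.17, 0.03]))
    ]
    return VariantRecord(
        variant_id=vid,
        chrom=chrom,
        pos=pos,
        ref_allele=str(_BASES[ref]),
        alt_allele=str(_BASES[alt]),
        gene=gene,
        impact=impact,
    )


def simulate_covariates(config: SimulationConfig, n: int | None = None) -> pd.DataFrame:
    """Uniform age/weight/height within configured ranges; sex Bernoulli(0.5)."""
    if n is None:
        n = config.n_samples
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng([_COV_STREAM, config.seed])
    out = {}
    for name in ("age", "weight", "height"):
        lo, hi = config.covariate_ranges[name]
        out[name] = rng.uniform(lo, hi, size=n)
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    df = pd.DataFrame(
        {"age": out["age"], "sex": sex, "weight": out["weight"], "height": out["height"]},
        index=[f"S{i + 1:04d}" for i in range(n)],
    )
    return df


def linear_predictor(
    genotypes: np.ndarray,
    variants: list[VariantRecord],
    covariates: pd.DataFrame,
    config: SimulationConfig,
) -> np.ndarray:
    """The true log-mean dose: intercept + covariate terms + genotype terms."""
    index = {v.variant_id: j for j, v in enumerate(variants)}
    n = len(covariates)
    eta = np.full(n, config.intercept)
    for name, eff in config.covariate_effects.items():
        if name == "sex":
            x = (covariates["sex"].to_numpy() == "male").astype(float)
        else:
            col = covariates[name].to_numpy(dtype=float)
            sd = col.std(ddof=1)
            x = (col - col.mean()) / sd if sd > 0 else np.zeros(n)
        eta = eta + eff * x
    for effect in config.true_effects:
        if isinstance(effect, GenotypeEffect):
            if effect.variant_id not in index:
                raise ValueError(f"true effect references unknown variant {effect.variant_id}")
            g = genotypes[:, index[effect.variant_id]]
            eta = eta + effect.effect * (g == effect.genotype_class)
        else:
            for vid in (effect.variant_id1, effect.variant_id2):
                if vid not in index:
                    raise ValueError(f"true effect references unknown variant {vid}")
            g1 = genotypes[:, index[effect.variant_id1]]
            g2 = genotypes[:, index[effect.variant_id2]]
            eta = eta + effect.effect * ((g1 == effect.class1) & (g2 == effect.class2))
    return eta


def simulate_doses(
    genotypes: np.ndarray,
    variants: list[VariantRecord],
    covariates: pd.DataFrame,
    config: SimulationConfig,
) -> pd.Series:
    """Dose_i ~ Gamma(shape, rate = shape/mu_i) so E[dose_i] = exp(eta_i)."""
    rng = np.random.default_rng([_DOSE_STREAM, config.seed])
    mu = np.exp(linear_predictor(genotypes, variants, covariates, config))
    doses = rng.gamma(shape=config.gamma_shape, scale=mu / config.gamma_shape)
    return pd.Series(doses, index=covariates.index, name="dose")


def simulate_cohort(config: SimulationConfig | None = None) -> tuple[Cohort, dict]:
    """Generate a full cohort plus a truth record of every generative choice."""
    if config is None:
        config = SimulationConfig()
    genotypes, variants = simulate_genotypes(config)
    covariates = simulate_covariates(config)
    dose = simulate_doses(genotypes, variants, covariates, config)
    cohort = Cohort(
        samples=list(covariates.index),
        genotypes=genotypes,
        variants=variants,
        covariates=covariates,
        dose=dose,
        dose_units=DoseUnits.MG_PER_WEEK,
    )
    truth = {
        "seed": config.seed,
        "intercept": config.intercept,
        "gamma_shape": config.gamma_shape,
        "covariate_effects": dict(config.covariate_effects),
        "true_effects": [
            {"kind": type(e).__name__, **asdict(e)} for e in config.true_effects
        ],
        "ld_pairs": [asdict(p) for p in config.ld_pairs],
    }
    return cohort, truth


def write_truth(path: str | Path, truth: dict) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)


def shape_for_target_r2(config: SimulationConfig, target_r2: float, n: int = 20_000) -> float:
    """Gamma shape making the generative log-scale R-squared equal target_r2.

    Var(log y | mu) = trigamma(shape) under the gamma model, so the shape is
    the trigamma inverse of signal_var * (1 - R2) / R2, with the signal
    variance measured on a large simulated cohort.
    """
    if not (0 < target_r2 < 1):
        raise ValueError("target_r2 must be in (0, 1)")
    big = SimulationConfig(**{**asdict_config(config), "n_samples": n})
    genotypes, variants = simulate_genotypes(big)
    covariates = simulate_covariates(big)
    eta = linear_predictor(genotypes, variants, covariates, big)
    signal = float(np.var(eta, ddof=1))
    noise = signal * (1 - target_r2) / target_r2
    f = lambda s: float(special.polygamma(1, s)) - noise
    return float(optimize.brentq(f, 1e-3, 1e6))


def asdict_config(config: SimulationConfig) -> dict:
    """Shallow dict of config fields preserving the effect dataclasses."""
    return {
        "n_samples": config.n_samples,
        "n_genes": config.n_genes,
        "snps_per_gene": config.snps_per_gene,
        "maf_range": config.maf_range,
        "novel_fraction": config.novel_fraction,
        "ld_pairs": config.ld_pairs,
        "anchor_variants": config.anchor_variants,
        "true_effects": config.true_effects,
        "covariate_effects": config.covariate_effects,
        "covariate_ranges": config.covariate_ranges,
        "intercept": config.intercept,
        "gamma_shape": config.gamma_shape,
        "seed": config.seed,
    }
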