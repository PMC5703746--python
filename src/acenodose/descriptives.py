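"""Descriptive pharmacogenetic statistics.

Allele frequencies and per-individual variant tallies, the Hardy-Weinberg
exact test with Benjamini-Hochberg FDR control, FST population
differentiation against user-supplied reference frequency tables
(Wright's and the Weir-Cockerham two-population estimator), per-gene
novel/known and impact summaries, and pairwise composite LD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .cohort import Cohort, ReferenceFrequencyTable, VariantRecord

log = logging.getLogger("acenodose")


# ---------------------------------------------------------------- summaries

def summarize_variants(cohort: Cohort) -> pd.DataFrame:
    """Per-variant counts, allele frequencies and Hardy-Weinberg tests.

    Returns a DataFrame indexed by variant_id with columns n_called, n_het,
    n_hom_alt, alt_freq, maf, hwe_p, hwe_q (BH-adjusted).  All-missing
    variants are excluded and logged.
    """
    rows = []
    for j, v in enumerate(cohort.variants):
        col = cohort.genotypes[:, j]
        called = col[~np.isnan(col)]
        if called.size == 0:
            log.warning("variant %s has no called genotypes; excluded", v.variant_id)
            continue
        n_called = called.size
        n_het = int((called == 1).sum())
        n_hom_alt = int((called == 2).sum())
        n_hom_ref = n_called - n_het - n_hom_alt
        alt_freq = (n_het + 2 * n_hom_alt) / (2 * n_called)
        rows.append(
            {
                "variant_id": v.variant_id,
                "gene": v.gene,
                "n_called": n_called,
                "n_het": n_het,
                "n_hom_alt": n_hom_alt,
                "alt_freq": alt_freq,
                "maf": min(alt_freq, 1 - alt_freq),
                "hwe_p": hwe_exact_test(n_het, n_hom_ref, n_hom_alt),
            }
        )
    df = pd.DataFrame(rows).set_index("variant_id")
    df["hwe_q"] = fdr_adjust(df["hwe_p"].to_numpy())
    return df


def per_individual_counts(cohort: Cohort) -> pd.DataFrame:
    """Per-sample tallies of heterozygous / homozygous-alt calls.

    Split into known (rs) and novel variants, mirroring resequencing summary
    tables of the form "908 SNVs per individual, 534 het and 374 hom".
    """
    known = np.array([v.known for v in cohort.variants])
    g = cohort.genotypes
    het = g == 1
    hom = g == 2
    out = pd.DataFrame(
        {
            "n_het": het.sum(axis=1),
            "n_hom_alt": hom.sum(axis=1),
            "n_variant_sites": (het | hom).sum(axis=1),
            "n_het_known": het[:, known].sum(axis=1),
            "n_hom_alt_known": hom[:, known].sum(axis=1),
            "n_het_novel": het[:, ~known].sum(axis=1),
            "n_hom_alt_novel": hom[:, ~known].sum(axis=1),
        },
        index=pd.Index(cohort.samples, name="sample"),
    )
    return out


# ------------------------------------------------------ Hardy-Weinberg test

def hwe_exact_test(n_het: int, n_hom_ref: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test (Wigginton-style).

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count (same parity) no more probable than the one
    observed.  Returns 1.0 for monomorphic sites.
    """
    for name, c in (("n_het", n_het), ("n_hom_ref", n_hom_ref), ("n_hom_alt", n_hom_alt)):
        if c < 0:
            raise ValueError(f"{name} must be >= 0, got {c}")
    n = n_het + n_hom_ref + n_hom_alt
    if n < 1:
        raise ValueError("at least one genotype required")
    n_rare = n_het + 2 * min(n_hom_ref, n_hom_alt)
    if n_rare == 0:
        return 1.0
    # unnormalized probabilities over all het counts with the parity of n_rare
    het_counts = list(range(n_rare % 2, n_rare + 1, 2))
    probs = np.zeros(len(het_counts))
    # start from the mid heterozygote count and apply the ratio recurrence
    mid = n_rare * (2 * n - n_rare) // (2 * n)
    if mid % 2 != n_rare % 2:
        mid += 1
    i_mid = het_counts.index(mid)
    probs[i_mid] = 1.0
    # going down: P(h-2)/P(h) = h (h-1) / (4 (r+1) (c+1)) with r, c the
    # rare/common homozygote counts at h
    for i in range(i_mid, 0, -1):
        h = het_counts[i]
        r = (n_rare - h) // 2
        c = n - h - r
        probs[i - 1] = probs[i] * h * (h - 1) / (4.0 * (r + 1) * (c + 1))
    for i in range(i_mid, len(het_counts) - 1):
        h = het_counts[i]
        r = (n_rare - h) // 2
        c = n - h - r
        probs[i + 1] = probs[i] * 4.0 * r * c / ((h + 1.0) * (h + 2.0))
    probs /= probs.sum()
    observed = n_het
    p_obs = probs[het_counts.index(observed)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-10)].sum()))


def hwe_chisq_test(n_het: int, n_hom_ref: int, n_hom_alt: int) -> float:
    """One-df chi-square Hardy-Weinberg test (no continuity correction)."""
    from scipy import stats

    n = n_het + n_hom_ref + n_hom_alt
    p = (n_het + 2 * n_hom_alt) / (2 * n)
    exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
    obs = np.array([n_hom_ref, n_het, n_hom_alt])
    keep = exp > 0
    stat = float(((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum())
    return float(stats.chi2.sf(stat, df=1))


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------- FST

@dataclass
class FstResult:
    variant_id: str
    population_pair: tuple[str, str]
    fst: float
    estimator: str
    flagged: bool = False


def fst_wright(p1: float, p2: float) -> tuple[float, bool]:
    """Wright's FST = (H_T - H_S)/H_T from two allele frequencies."""
    hs = (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2.0
    pbar = (p1 + p2) / 2.0
    ht = 2 * pbar * (1 - pbar)
    if ht == 0:
        return 0.0, True
    return (ht - hs) / ht, False


def fst_weir_cockerham(
    p1: float,
    n1: float,
    p2: float,
    n2: float,
    h1: float | None = None,
    h2: float | None = None,
) -> tuple[float, bool]:
    """Two-population single-locus Weir-Cockerham theta.

    n1, n2 are diploid sample sizes; h1, h2 observed heterozygote
    proportions (Hardy-Weinberg expectation assumed when omitted).  May be
    slightly negative; callers flag rather than floor.
    """
    if h1 is None:
        h1 = 2 * p1 * (1 - p1)
    if h2 is None:
        h2 = 2 * p2 * (1 - p2)
    r = 2
    nbar = (n1 + n2) / 2.0
    if nbar <= 1:
        return 0.0, True
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    pq = pbar * (1 - pbar)
    a = (nbar / nc) * (s2 - (pq - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pq - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2.0
    denom = a + b + c
    if denom == 0:
        return 0.0, True
    return a / denom, False


def fst(
    variant_id: str,
    p1: float,
    n1: float,
    p2: float,
    n2: float,
    populations: tuple[str, str] = ("cohort", "reference"),
    estimator: str = "weir_cockerham",
    h1: float | None = None,
    h2: float | None = None,
) -> FstResult:
    if estimator == "wright":
        value, flagged = fst_wright(p1, p2)
    elif estimator == "weir_cockerham":
        value, flagged = fst_weir_cockerham(p1, n1, p2, n2, h1=h1, h2=h2)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return FstResult(variant_id, populations, float(value), estimator, flagged)


def differentiation_screen(
    cohort: Cohort,
    reference: ReferenceFrequencyTable,
    threshold: float = 0.25,
    estimator: str = "weir_cockerham",
) -> dict[str, pd.DataFrame]:
    """Per reference population: FST of shared variants, sorted descending.

    Each table carries a boolean ``above_threshold``; the screen mirrors the
    style of reports such as "377 variants with FST above 0.25 vs YRI".
    """
    summary = summarize_variants(cohort)
    results: dict[str, pd.DataFrame] = {}
    any_shared = False
    for pop in reference.populations:
        ref = reference.for_population(pop)
        shared = [vid for vid in summary.index if vid in ref.index]
        if not shared:
            continue
        any_shared = True
        rows = []
        for vid in shared:
            s = summary.loc[vid]
            res = fst(
                vid,
                float(s["alt_freq"]),
                float(s["n_called"]),
                float(ref.loc[vid, "alt_freq"]),
                float(ref.loc[vid, "n_chromosomes"]) / 2.0,
                populations=("cohort", pop),
                estimator=estimator,
                h1=float(s["n_het"] / s["n_called"]),
            )
            rows.append({"variant_id": vid, "fst": res.fst, "flagged": res.flagged})
        df = pd.DataFrame(rows).set_index("variant_id").sort_values("fst", ascending=False)
        df["above_threshold"] = df["fst"] > threshold
        results[pop] = df
    if not any_shared:
        raise ValueError("no variant IDs shared between cohort and reference table")
    return results


# ---------------------------------------------------- novelty/impact table

def novelty_impact_summary(
    variants: list[VariantRecord],
    maf: dict[str, float] | pd.Series,
    maf_cutoff: float = 0.01,
) -> pd.DataFrame:
    """Per-gene novel/known counts, ratio, impact-class tallies and the
    count of novel variants above the MAF cutoff."""
    maf = pd.Series(maf)
    rows: dict[str, dict] = {}
    for v in variants:
        row = rows.setdefault(
            v.gene,
            {
                "n_known": 0,
                "n_novel": 0,
                "n_high": 0,
                "n_moderate": 0,
                "n_modifier": 0,
                "n_low": 0,
                "n_unknown": 0,
                "n_novel_common": 0,
            },
        )
        row["n_known" if v.known else "n_novel"] += 1
        row[f"n_{v.impact.value}"] += 1
        if not v.known and float(maf.get(v.variant_id, 0.0)) > maf_cutoff:
            row["n_novel_common"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index").rename_axis("gene")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = df["n_novel"] / df["n_known"]
    df["novel_to_known_ratio"] = np.where(df["n_novel"] == 0, 0.0, ratio)
    return df.sort_index()


# ----------------------------------------------------------------------- LD

def ld_r(g1: np.ndarray, g2: np.ndarray) -> tuple[float, float]:
    """Composite LD: Pearson r of alt-allele counts, and r-squared.

    Phase-free (genotype-based) correlation; raises if either locus has no
    variance among jointly called samples.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = ~(np.isnan(g1) | np.isnan(g2))
    if ok.sum() < 2:
        raise ValueError("need >= 2 samples called at both loci")
    a, b = g1[ok], g2[ok]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero genotype variance at one locus; LD undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    return r, r * r


# -------------------------------------------------------------- TSV writers

def write_tsv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t")


def write_differentiation_report(path: str | Path, screen: dict[str, pd.DataFrame]) -> None:
    frames = []
    for pop, df in screen.items():
        d = df.copy()
        d.insert(0, "population", pop)
        frames.append(d)
    pd.concat(frames).to_csv(path, sep="\t")
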