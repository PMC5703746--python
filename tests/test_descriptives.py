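"""Descriptive statistics against independent oracles and hand cases."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special

import acenodose as ad
from acenodose.descriptives import fst_weir_cockerham, fst_wright

from conftest import make_cohort


# ------------------------------------------------ Hardy-Weinberg exact test

def hwe_oracle(n_het, n_hom_ref, n_hom_alt):
    """Direct enumeration: multinomial weights n! / (r! h! c!) * 2^h over
    all heterozygote counts compatible with the allele counts."""
    n = n_het + n_hom_ref + n_hom_alt
    n_rare = n_het + 2 * min(n_hom_ref, n_hom_alt)
    weights = {}
    for h in range(n_rare % 2, n_rare + 1, 2):
        r = (n_rare - h) // 2
        c = n - h - r
        if r < 0 or c < 0:
            continue
        logw = (special.gammaln(n + 1) - special.gammaln(r + 1)
                - special.gammaln(h + 1) - special.gammaln(c + 1)
                + h * np.log(2))
        weights[h] = logw
    mx = max(weights.values())
    probs = {h: np.exp(w - mx) for h, w in weights.items()}
    total = sum(probs.values())
    p_obs = probs[n_het] / total
    return sum(p for p in (v / total for v in probs.values())
               if p <= p_obs * (1 + 1e-10))


def test_hwe_monomorphic_is_one():
    assert ad.hwe_exact_test(0, 42, 0) == 1.0
    assert ad.hwe_exact_test(0, 0, 17) == 1.0


@pytest.mark.parametrize("het,hom_ref,hom_alt", [
    (50, 25, 25),
    (100, 0, 0),
    (3, 90, 7),
    (1, 1, 1),
])
def test_hwe_matches_enumeration(het, hom_ref, hom_alt):
    expected = hwe_oracle(het, hom_ref, hom_alt)
    assert ad.hwe_exact_test(het, hom_ref, hom_alt) == pytest.approx(expected, rel=1e-9)


def test_hwe_all_het_is_extreme():
    assert ad.hwe_exact_test(100, 0, 0) < 1e-10


def test_hwe_rejects_negative_counts():
    with pytest.raises(ValueError):
        ad.hwe_exact_test(-1, 5, 5)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
def test_hwe_enumeration_equivalence_small_tables(het, hom_ref, hom_alt):
    """Exact-test p equals brute-force enumeration on all tables n <= 50."""
    if het + hom_ref + hom_alt == 0 or het + hom_ref + hom_alt > 50:
        return
    assert ad.hwe_exact_test(het, hom_ref, hom_alt) == pytest.approx(
        hwe_oracle(het, hom_ref, hom_alt), rel=1e-9)


# --------------------------------------------------------------------- FDR

def bh_oracle(p):
    """Brute-force Benjamini-Hochberg step-up."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def test_fdr_hand_case():
    np.testing.assert_allclose(ad.fdr_adjust([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04])


def test_fdr_degenerate_cases():
    np.testing.assert_allclose(ad.fdr_adjust([1.0, 1.0, 1.0]), [1, 1, 1])
    np.testing.assert_allclose(ad.fdr_adjust([0.3]), [0.3])
    with pytest.raises(ValueError):
        ad.fdr_adjust([0.0, 0.5])


def test_fdr_matches_bruteforce_on_random_vectors():
    rng = np.random.default_rng(0)
    for _ in range(20):
        p = rng.uniform(1e-6, 1, size=rng.integers(1, 40))
        np.testing.assert_allclose(ad.fdr_adjust(p), bh_oracle(p), atol=1e-12)


# --------------------------------------------------------------------- FST

def test_wright_fst_hand_cases():
    assert fst_wright(0.3, 0.3) == (0.0, False)
    assert fst_wright(0.0, 1.0)[0] == pytest.approx(1.0)
    # H_S = 0.32, H_T = 0.5
    assert fst_wright(0.2, 0.8)[0] == pytest.approx(0.36)


def test_wright_fst_monomorphic_flagged():
    value, flagged = fst_wright(0.0, 0.0)
    assert value == 0.0 and flagged


def test_wright_fst_bounded():
    rng = np.random.default_rng(1)
    for _ in range(200):
        p1, p2 = rng.uniform(0, 1, 2)
        v, _ = fst_wright(p1, p2)
        assert -1e-12 <= v <= 1 + 1e-12


def test_both_estimators_vanish_as_frequencies_converge():
    for eps in (0.05, 0.01, 0.001):
        w, _ = fst_wright(0.4, 0.4 + eps)
        wc, _ = fst_weir_cockerham(0.4, 100, 0.4 + eps, 100)
        assert abs(w) < 0.01
        assert wc < 0.01
    assert fst_wright(0.4, 0.4)[0] == 0.0


def test_differentiation_screen_counts():
    """Cohort-identical reference yields nothing; forced fixed differences
    are all recovered; an impossible threshold yields an empty set."""
    rng = np.random.default_rng(3)
    n = 60
    g = rng.binomial(2, 0.4, size=(n, 15)).astype(float)
    g[:, :10] = 2.0   # fixed alt in the cohort
    cohort = make_cohort(g)
    summary = ad.summarize_variants(cohort)
    ids = list(summary.index)
    same = ad.ReferenceFrequencyTable(pd.DataFrame({
        "population": "SAME", "variant_id": ids,
        "alt_freq": summary["alt_freq"].to_numpy(), "n_chromosomes": 2 * n}))
    screen = ad.differentiation_screen(cohort, same, estimator="wright")
    assert screen["SAME"]["above_threshold"].sum() == 0

    freqs = summary["alt_freq"].to_numpy().copy()
    freqs[:10] = 0.0  # fixed difference at the first ten variants
    diff = ad.ReferenceFrequencyTable(pd.DataFrame({
        "population": "FAR", "variant_id": ids,
        "alt_freq": freqs, "n_chromosomes": 2 * n}))
    screen = ad.differentiation_screen(cohort, diff, estimator="wright")
    above = screen["FAR"][screen["FAR"]["above_threshold"]]
    assert set(above.index) == set(ids[:10])
    screen_hi = ad.differentiation_screen(cohort, diff, threshold=1.01,
                                          estimator="wright")
    assert screen_hi["FAR"]["above_threshold"].sum() == 0


def test_differentiation_screen_requires_shared_variants():
    cohort = make_cohort(np.array([[0, 1], [1, 2]], dtype=float))
    ref = ad.ReferenceFrequencyTable(pd.DataFrame({
        "population": ["X"], "variant_id": ["rs_not_here"],
        "alt_freq": [0.5], "n_chromosomes": [100]}))
    with pytest.raises(ValueError, match="shared"):
        ad.differentiation_screen(cohort, ref)


# ---------------------------------------------------------------- summaries

def test_summarize_variants_frequencies():
    """50 het + 25 hom-alt of 100 samples gives alt freq 0.5; a monomorphic
    reference column gives MAF 0."""
    col = np.array([1] * 50 + [2] * 25 + [0] * 25, dtype=float)
    mono = np.zeros(100)
    cohort = make_cohort(np.column_stack([col, mono]))
    s = ad.summarize_variants(cohort)
    assert s.loc["rs1", "alt_freq"] == pytest.approx(0.5)
    assert s.loc["rs1", "n_het"] == 50 and s.loc["rs1", "n_hom_alt"] == 25
    assert s.loc["rs2", "maf"] == 0.0


def test_summary_counts_are_sample_order_invariant():
    rng = np.random.default_rng(5)
    g = rng.binomial(2, 0.3, size=(40, 8)).astype(float)
    a = ad.summarize_variants(make_cohort(g))
    b = ad.summarize_variants(make_cohort(g[rng.permutation(40)]))
    pd.testing.assert_frame_equal(a, b)


def test_per_individual_tally_matches_construction():
    """A crafted single-sample cohort with 534 het + 374 hom-alt entries
    tallies exactly (534, 374) — the published per-individual pattern."""
    g = np.array([[1] * 534 + [2] * 374 + [0] * 92], dtype=float)
    cohort = make_cohort(g)
    tallies = ad.per_individual_counts(cohort)
    assert tallies.loc["S0", "n_het"] == 534
    assert tallies.loc["S0", "n_hom_alt"] == 374
    assert tallies.loc["S0", "n_variant_sites"] == 908


def test_novelty_impact_summary():
    variants = (
        [ad.VariantRecord(f"rs{i}", "chr1", i + 1, "A", "G", gene="SULT1A1")
         for i in range(63)]
        + [ad.VariantRecord(f"POS{i + 1000}", "chr1", i + 1000, "A", "G",
                            gene="SULT1A1") for i in range(19)]
        + [ad.VariantRecord("rs9000", "chr2", 5, "A", "G", gene="NONOVEL")]
    )
    maf = {v.variant_id: 0.2 for v in variants}
    table = ad.novelty_impact_summary(variants, maf)
    assert table.loc["SULT1A1", "n_known"] == 63
    assert table.loc["SULT1A1", "n_novel"] == 19
    assert table.loc["SULT1A1", "novel_to_known_ratio"] == pytest.approx(19 / 63)
    assert table.loc["NONOVEL", "novel_to_known_ratio"] == 0.0


def test_novelty_maf_cutoff_filter():
    variants = [ad.VariantRecord(f"POS{i}", "chr1", i, "A", "G", gene="G1")
                for i in (10, 20, 30)]
    maf = {"POS10": 0.005, "POS20": 0.02, "POS30": 0.10}
    table = ad.novelty_impact_summary(variants, maf, maf_cutoff=0.01)
    assert table.loc["G1", "n_novel_common"] == 2


# ----------------------------------------------------------------------- LD

def test_ld_r_trivial_cases():
    g = np.array([0, 1, 2, 1, 0, 2], dtype=float)
    r, r2 = ad.ld_r(g, g)
    assert r == pytest.approx(1.0) and r2 == pytest.approx(1.0)
    r, _ = ad.ld_r(g, 2 - g)
    assert r == pytest.approx(-1.0)
    with pytest.raises(ValueError, match="variance"):
        ad.ld_r(g, np.ones_like(g))
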