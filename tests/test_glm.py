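"""The Bayesian gamma GLM: likelihood, diagnostics, HDIs, and sampler
correctness (prior recovery, reproducibility, contraction, recovery)."""

import numpy as np
import pytest
from scipy import stats

import acenodose as ad
from acenodose.design import DesignMatrix, Term, TermGroup
from acenodose.glm import _chain_seed


# ----------------------------------------------------------- log-likelihood

def test_loglik_exponential_closed_form():
    """shape tau = 1 reduces to the exponential log-density -log mu - y/mu."""
    y = np.array([0.5, 2.0, 3.7])
    eta = np.array([0.1, -0.3, 1.2])
    mu = np.exp(eta)
    expected = np.sum(-np.log(mu) - y / mu)
    assert ad.log_likelihood(y, eta, 1.0) == pytest.approx(expected, rel=1e-12)


def test_loglik_concentrates_at_mean_as_shape_grows():
    y = np.array([2.0])
    eta = np.log(y)
    values = [ad.log_likelihood(y, eta, tau) for tau in (1, 10, 100, 1000)]
    assert all(b > a for a, b in zip(values, values[1:]))


def test_loglik_link_shift_consistency():
    """Shifting the intercept by delta multiplies all means by exp(delta)."""
    rng = np.random.default_rng(0)
    y = rng.gamma(5, 1, size=50)
    eta = rng.normal(0, 0.5, size=50)
    delta = 0.37
    assert ad.log_likelihood(y, eta + delta, 4.0) == pytest.approx(
        ad.log_likelihood(y, np.log(np.exp(eta) * np.exp(delta)), 4.0), rel=1e-12)


def test_loglik_rejects_nonfinite_predictor():
    with pytest.raises(ValueError, match="sample"):
        ad.log_likelihood(np.array([1.0, 2.0]), np.array([0.0, np.inf]), 1.0)


# ------------------------------------------------------------- Gelman-Rubin

def gelman_rubin_oracle(x):
    """Independent textbook formulation from chain means and variances."""
    m, n = x.shape
    chain_means = x.mean(axis=1)
    grand = chain_means.mean()
    b = n / (m - 1) * np.sum((chain_means - grand) ** 2)
    w = np.mean([np.sum((x[i] - chain_means[i]) ** 2) / (n - 1) for i in range(m)])
    var_hat = (n - 1) / n * w + b / n
    return np.sqrt(var_hat / w)


def test_gelman_rubin_identical_chains_near_one():
    rng = np.random.default_rng(1)
    chain = rng.normal(0, 1, 500)
    x = np.tile(chain, (4, 1))
    assert ad.gelman_rubin(x) <= 1 + 1e-6


def test_gelman_rubin_disjoint_chains_large():
    rng = np.random.default_rng(2)
    x = np.vstack([rng.normal(0, 1, 200), rng.normal(100, 1, 200)])
    assert ad.gelman_rubin(x) > 10


def test_gelman_rubin_matches_oracle():
    rng = np.random.default_rng(3)
    for _ in range(10):
        x = rng.normal(rng.normal(0, 0.3, (5, 1)), 1, size=(5, 300))
        assert ad.gelman_rubin(x) == pytest.approx(gelman_rubin_oracle(x), abs=1e-10)


def test_gelman_rubin_zero_variance_flagged():
    assert np.isnan(ad.gelman_rubin(np.ones((3, 50))))


# ---------------------------------------------------------------------- HDI

def test_hdi_uniform_width():
    rng = np.random.default_rng(4)
    lo, hi = ad.hdi(rng.uniform(0, 1, 100_000), 0.95)
    assert (hi - lo) == pytest.approx(0.95, abs=0.02)


def test_hdi_normal_quantiles():
    rng = np.random.default_rng(5)
    lo, hi = ad.hdi(rng.normal(0, 1, 100_000), 0.95)
    assert lo == pytest.approx(-1.96, abs=0.05)
    assert hi == pytest.approx(1.96, abs=0.05)


def test_hdi_constant_draws():
    assert ad.hdi(np.full(500, 3.25)) == (3.25, 3.25)


# ----------------------------------------------------- sampler correctness

def _null_design(n):
    """One indicator group with an all-zero column: no information."""
    return DesignMatrix(
        samples=[f"S{i}" for i in range(n)],
        covariate_names=[], X_cov=np.empty((n, 0)),
        cov_means=np.empty(0), cov_sds=np.empty(0),
        X_terms=np.zeros((n, 1)),
        terms=[Term(0, "main", ("rsZ",), (1,), "G", "rsZ:het", 0)],
        groups=[TermGroup(0, "snp", ("rsZ",), "G", (0,))],
    )


def test_intercept_recovery_and_uninformative_pip():
    """On y ~ Gamma(5, rate 5/e) the intercept's 95% HDI covers c = 1 and
    an all-zero term column keeps its prior inclusion probability."""
    rng = np.random.default_rng(42)
    n = 500
    c_true, tau_true = 1.0, 5.0
    y = rng.gamma(tau_true, np.exp(c_true) / tau_true, size=n)
    design = _null_design(n)
    spec = ad.ModelSpec()
    samples = ad.fit_mcmc(design, y, spec,
                          ad.McmcSettings(n_chains=3, n_iterations=8000,
                                          n_burnin=1000, thinning=2, seed=9))
    lo, hi = ad.hdi(samples.c.ravel())
    assert lo < c_true < hi
    pip = float(samples.group_pip()[0])
    assert pip == pytest.approx(spec.prior_inclusion, abs=0.02)
    lo_t, hi_t = ad.hdi(samples.tau.ravel())
    assert lo_t < tau_true < hi_t


def test_same_seed_reproduces_draws(small_cohort):
    cohort, _ = small_cohort
    design = ad.default_design(cohort)
    settings = ad.McmcSettings(n_chains=2, n_iterations=1500, n_burnin=500,
                               thinning=5, seed=21)
    a = ad.fit_mcmc(design, cohort.dose.to_numpy(), ad.ModelSpec(), settings)
    b = ad.fit_mcmc(design, cohort.dose.to_numpy(), ad.ModelSpec(), settings)
    np.testing.assert_array_equal(a.c, b.c)
    np.testing.assert_array_equal(a.beta, b.beta)
    np.testing.assert_array_equal(a.inc, b.inc)
    np.testing.assert_array_equal(a.tau, b.tau)


def test_chain_seeds_stay_below_2_31():
    for base in (0, 1, 123456, 2**31 - 1):
        for ch in range(6):
            assert 0 < _chain_seed(base, ch) < 2**31


def test_prior_recovery_with_likelihood_disabled(small_cohort):
    """With the likelihood off, the kernel's marginals match the stated
    priors (KS < 0.05) and P(I = 1) matches E[pi]."""
    cohort, _ = small_cohort
    design = ad.default_design(cohort).subset_groups(range(20))
    spec = ad.ModelSpec()
    samples = ad.fit_mcmc(design, cohort.dose.to_numpy(), spec,
                          ad.McmcSettings(n_chains=4, n_iterations=14_000,
                                          n_burnin=1000, thinning=2, seed=3),
                          likelihood_on=False)
    c = samples.c.ravel()
    assert stats.kstest(c, "norm", args=(0, np.sqrt(spec.tau_mu2))).statistic < 0.05
    assert stats.kstest(samples.pi.ravel(), "uniform",
                        args=(spec.a, spec.b - spec.a)).statistic < 0.05
    assert stats.kstest(samples.tau.ravel(), "gamma",
                        args=(spec.lam, 0, 1 / spec.kap)).statistic < 0.05
    pool = np.concatenate([samples.conditional_beta(j)
                           for j in range(design.n_term_columns)])
    assert pool.size > 2000
    assert stats.kstest(pool, "laplace", args=(0, spec.tau_beta)).statistic < 0.05
    assert samples.group_pip().mean() == pytest.approx(spec.prior_inclusion, abs=0.01)


def _focused_config(seed, n, effect):
    return ad.SimulationConfig(
        seed=seed, n_samples=n, n_genes=3, snps_per_gene=(2, 4),
        ld_pairs=[], covariate_effects={},
        anchor_variants=[("CYP2D8P", "POS42547668", 0.15),
                         ("SULT1A1", "rs11648192", 0.30)],
        true_effects=([ad.GenotypeEffect("POS42547668", 1, effect)]
                      if effect else []),
    )


def _fit_focused(cfg, seed):
    cohort, _ = ad.simulate_cohort(cfg)
    design = ad.default_design(cohort)
    samples = ad.fit_mcmc(design, cohort.dose.to_numpy(), ad.ModelSpec(),
                          ad.McmcSettings(n_chains=2, n_iterations=4000,
                                          n_burnin=1000, thinning=5, seed=seed))
    col = next(t.column for t in design.terms
               if t.kind == "main" and t.variants == ("POS42547668",)
               and t.classes == (1,))
    return samples, design, col


def test_posterior_contraction_with_sample_size():
    """Doubling n shrinks the HDI width of a truly included effect
    (in expectation over seeds)."""
    widths = {100: [], 200: []}
    for n in widths:
        for seed in range(1, 7):
            samples, design, col = _fit_focused(_focused_config(seed, n, 0.899), seed)
            cond = samples.conditional_beta(col)
            if cond.size >= 50:
                lo, hi = ad.hdi(cond)
                widths[n].append(hi - lo)
    assert len(widths[100]) >= 4 and len(widths[200]) >= 4
    assert np.mean(widths[200]) < np.mean(widths[100])


def test_pip_monotone_in_effect_size():
    """PIP is non-decreasing in |true effect| (Monte-Carlo slack 0.05)."""
    grid = [0.0, 0.45, 0.9]
    mean_pips = []
    for effect in grid:
        pips = []
        for seed in range(1, 6):
            samples, design, col = _fit_focused(_focused_config(seed, 100, effect), seed)
            pips.append(samples.column_pip()[col])
        mean_pips.append(np.mean(pips))
    assert mean_pips[1] >= mean_pips[0] - 0.05
    assert mean_pips[2] >= mean_pips[1] - 0.05
    assert mean_pips[2] > 0.5


def test_large_effect_inside_hdi_across_replicates():
    """A true log-scale effect of magnitude ~0.9 at n = 100 falls inside
    its conditional 95% HDI in >= 90% of 20 scaled-down replicates."""
    hits = total = 0
    for seed in range(1, 21):
        samples, design, col = _fit_focused(_focused_config(seed, 100, 0.899), seed)
        cond = samples.conditional_beta(col)
        if cond.size < 50:
            continue
        total += 1
        lo, hi = ad.hdi(cond)
        hits += lo <= 0.899 <= hi
    assert total >= 15
    assert hits / total >= 0.9


def test_nonconvergence_is_flagged(small_cohort):
    """Absurdly short chains must set the convergence flag rather than
    fail silently."""
    cohort, _ = small_cohort
    design = ad.default_design(cohort).subset_groups(range(10))
    samples = ad.fit_mcmc(design, cohort.dose.to_numpy(), ad.ModelSpec(),
                          ad.McmcSettings(n_chains=3, n_iterations=60,
                                          n_burnin=10, thinning=1, seed=1))
    assert isinstance(samples.converged, bool)
    assert samples.rhat   # diagnostics always populated


def test_summarize_posterior_report(small_fit):
    cohort, design, samples = small_fit
    report = ad.summarize_posterior(samples)
    assert len(report) == 1 + len(design.covariate_names) + len(design.terms)
    assert report.iloc[0]["term"] == "intercept"
    # natural-unit back-transform: standardized coef / covariate sd
    age_row = report[report["term"] == "age"].iloc[0]
    sd = cohort.covariates["age"].std(ddof=1)
    assert age_row["mean_natural"] == pytest.approx(age_row["mean"] / sd)
    tail = report.iloc[1 + len(design.covariate_names):]
    assert (tail["pip"].to_numpy()[:-1] >= tail["pip"].to_numpy()[1:]).all()


def test_posterior_samples_persistence(tmp_path, small_fit):
    _, design, samples = small_fit
    samples.save(tmp_path / "draws")
    assert (tmp_path / "draws" / "manifest.json").exists()
    import json
    manifest = json.loads((tmp_path / "draws" / "manifest.json").read_text())
    assert manifest["n_chains"] == samples.c.shape[0]
    import pandas as pd
    chain0 = pd.read_csv(tmp_path / "draws" / "chain0.csv")
    np.testing.assert_allclose(chain0["c"].to_numpy(), samples.c[0])
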