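"""Bayes factors, the conditioned decision tree, DIC and prediction
comparison."""

import numpy as np
import pandas as pd
import pytest

import acenodose as ad
from acenodose.design import DesignMatrix, Term, TermGroup
from acenodose.glm import McmcSettings, ModelSpec, PosteriorSamples
from acenodose.selection import (
    bayes_factor_from_pip,
    cutoff,
    format_bayes_factor,
)


# ------------------------------------------------------------ BF arithmetic

def test_bayes_factor_identity():
    """BF = (q/(1-q)) / prior odds exactly."""
    prior = 0.0505
    odds = prior / (1 - prior)
    for q in (0.1, 0.5, 0.9):
        assert bayes_factor_from_pip(q, prior) == pytest.approx(
            (q / (1 - q)) / odds, rel=1e-12)


def test_bayes_factor_no_evidence_is_one():
    assert bayes_factor_from_pip(0.0505, 0.0505) == pytest.approx(1.0)


def test_bayes_factor_certain_inclusion_capped():
    bf = bayes_factor_from_pip(1.0, 0.0505)
    assert np.isinf(bf)
    assert format_bayes_factor(bf) == ">900"
    assert format_bayes_factor(901.0) == ">900"
    assert format_bayes_factor(12.34) == "12.34"


def test_cutoff_rule_arithmetic():
    """c_j = 3 + m_j: conditioning two terms absent raises the cutoff to 5."""
    assert cutoff(0) == 3.0
    assert cutoff(1) == 4.0
    assert cutoff(2) == 5.0


# --------------------------------------------- synthetic posterior helpers

def _design_two_groups(n=20):
    rng = np.random.default_rng(0)
    X = rng.binomial(1, 0.4, size=(n, 2)).astype(float)
    return DesignMatrix(
        samples=[f"S{i}" for i in range(n)],
        covariate_names=[], X_cov=np.empty((n, 0)),
        cov_means=np.empty(0), cov_sds=np.empty(0),
        X_terms=X,
        terms=[Term(0, "main", ("rsA",), (1,), "GA", "rsA:het", 0),
               Term(1, "main", ("rsB",), (1,), "GB", "rsB:het", 1)],
        groups=[TermGroup(0, "snp", ("rsA",), "GA", (0,)),
                TermGroup(1, "snp", ("rsB",), "GB", (1,))],
    )


def _samples_from_inc(inc, beta=None, design=None, c=0.5, tau=5.0):
    """PosteriorSamples with prescribed indicator draws (1 chain)."""
    inc = np.asarray(inc, dtype=np.int8)[None, :, :]
    S, G = inc.shape[1], inc.shape[2]
    design = design or _design_two_groups()
    p = design.n_term_columns
    if beta is None:
        beta = np.zeros((1, S, p))
        for g in range(G):
            for col in design.groups[g].columns:
                beta[0, :, col] = 0.3 * inc[0, :, g]
    settings = McmcSettings(n_chains=2, n_iterations=S * 2 + 10, n_burnin=10,
                            thinning=2, seed=0)
    return PosteriorSamples(
        design=design, spec=ModelSpec(), settings=settings,
        c=np.full((1, S), c), alpha=np.empty((1, S, 0)),
        beta=beta, inc=inc, pi=np.full((1, S), 0.05),
        tau=np.full((1, S), tau),
    )


def test_conditioned_bayes_factor_matches_hand_arithmetic():
    """Conditioning restricts the draw subset; BF follows from the
    conditional inclusion fraction by hand."""
    S = 1000
    rng = np.random.default_rng(1)
    inc_b = rng.binomial(1, 0.5, S)
    # A is included 80% of the time when B is in, 20% when B is out
    inc_a = np.where(inc_b == 1, rng.binomial(1, 0.8, S), rng.binomial(1, 0.2, S))
    samples = _samples_from_inc(np.column_stack([inc_a, inc_b]))
    prior = samples.spec.prior_inclusion
    odds = prior / (1 - prior)
    q1 = inc_a[inc_b == 1].mean()
    bf = ad.bayes_factor_inclusion(samples, 0, conditioning=((1, 1),))
    assert bf == pytest.approx((q1 / (1 - q1)) / odds, rel=1e-12)
    q0 = inc_a[inc_b == 0].mean()
    bf0 = ad.bayes_factor_inclusion(samples, 0, conditioning=((1, 0),))
    assert bf0 == pytest.approx((q0 / (1 - q0)) / odds, rel=1e-12)


def test_conditioning_starvation_raises():
    inc = np.zeros((300, 2), dtype=int)
    inc[:5, 1] = 1
    samples = _samples_from_inc(inc)
    with pytest.raises(ValueError, match="longer chains"):
        ad.bayes_factor_inclusion(samples, 0, conditioning=((1, 1),))


# ------------------------------------------------------------------- tree

def test_tree_determinism(small_fit):
    _, _, samples = small_fit
    t1 = ad.build_decision_tree(samples)
    t2 = ad.build_decision_tree(samples)
    assert t1.to_json() == t2.to_json()


def test_tree_retains_strong_term_and_applies_cutoff():
    """A term included in ~all draws roots the tree; its children carry the
    raised cutoff on the conditioned-absent branch."""
    S = 2000
    rng = np.random.default_rng(2)
    inc_a = np.ones(S, dtype=int)                      # certain inclusion
    inc_b = rng.binomial(1, 0.05, S)                   # noise-level term
    samples = _samples_from_inc(np.column_stack([inc_a, inc_b]))
    tree = ad.build_decision_tree(samples, min_draws=50)
    assert tree.root is not None
    assert tree.root.group == 0
    assert tree.root.cutoff == 3.0
    # B's BF ~1 clears no cutoff, so no children are retained
    assert tree.root.children == []
    assert tree.retained_groups() == [0]


def test_tree_never_condition_blocks_branching():
    S = 2000
    rng = np.random.default_rng(3)
    inc = np.column_stack([np.ones(S, dtype=int), rng.binomial(1, 0.9, S)])
    samples = _samples_from_inc(inc)
    full = ad.build_decision_tree(samples, min_draws=50)
    blocked = ad.build_decision_tree(samples, min_draws=50,
                                     never_condition=("GA",))
    assert full.root.children   # branches exist when conditioning is allowed
    assert blocked.root.children == []


def test_tree_serialization_roundtrip(small_fit):
    import json
    _, _, samples = small_fit
    tree = ad.build_decision_tree(samples)
    payload = json.loads(tree.to_json())
    assert payload["cutoff_base"] == 3.0
    text = tree.render()
    assert isinstance(text, str) and text
    assert tree.to_dot().startswith("digraph")


# -------------------------------------------------------------------- DIC

def test_dic_degenerate_posterior_is_pointwise_deviance():
    """All draws identical: p_D = 0 so DIC equals the deviance at that
    point."""
    design = _design_two_groups()
    S = 400
    inc = np.ones((S, 2), dtype=int)
    beta = np.full((1, S, 2), 0.25)
    samples = _samples_from_inc(inc, beta=beta, design=design, c=0.8, tau=4.0)
    rng = np.random.default_rng(4)
    eta = 0.8 + design.X_terms @ np.array([0.25, 0.25])
    y = rng.gamma(4.0, np.exp(eta) / 4.0)
    value = ad.dic(samples, design, y)
    expected = -2.0 * ad.log_likelihood(y, eta, 4.0)
    assert value == pytest.approx(expected, rel=1e-9)


def test_dic_unchanged_by_all_zero_column(small_fit):
    """Appending an always-excluded zero column cannot move the DIC."""
    _, design, samples = small_fit
    cohort, _, _ = small_fit
    y = cohort.dose.to_numpy()
    base = ad.dic(samples, design, y)
    n, p = design.X_terms.shape
    padded = DesignMatrix(
        samples=design.samples, covariate_names=design.covariate_names,
        X_cov=design.X_cov, cov_means=design.cov_means, cov_sds=design.cov_sds,
        X_terms=np.hstack([design.X_terms, np.zeros((n, 1))]),
        terms=design.terms + [Term(p, "main", ("rsZ",), (1,), "Z", "rsZ:het",
                                   len(design.groups))],
        groups=design.groups + [TermGroup(len(design.groups), "snp", ("rsZ",),
                                          "Z", (p,))],
    )
    sam2 = PosteriorSamples(
        design=padded, spec=samples.spec, settings=samples.settings,
        c=samples.c, alpha=samples.alpha,
        beta=np.concatenate([samples.beta,
                             np.zeros(samples.beta.shape[:2] + (1,))], axis=2),
        inc=np.concatenate([samples.inc,
                            np.zeros(samples.inc.shape[:2] + (1,), dtype=np.int8)],
                           axis=2),
        pi=samples.pi, tau=samples.tau,
    )
    assert ad.dic(sam2, padded, y) == pytest.approx(base, rel=1e-9)


# -------------------------------------------------------- variance explained

def test_variance_explained_limits():
    rng = np.random.default_rng(5)
    y = rng.gamma(5, 1, 50)
    assert ad.variance_explained(np.log(y), y) == pytest.approx(100.0)
    assert ad.variance_explained(np.full(50, 1.3), y) == 0.0


def test_variance_explained_deviance_option():
    rng = np.random.default_rng(6)
    y = rng.gamma(5, 1, 200)
    perfect = ad.variance_explained(np.log(y), y, method="deviance")
    assert perfect == pytest.approx(100.0)
    assert ad.variance_explained(np.full(200, np.log(y).mean()), y,
                                 method="deviance") == pytest.approx(0.0, abs=1e-9)


# -------------------------------------------- predicted-vs-observed checks

def test_compare_identical_predictions_degenerate():
    obs = np.linspace(1, 4, 10)
    res = ad.compare_predicted_observed(obs, obs)
    assert res.degenerate and res.p_value == 1.0


def test_compare_flags_gross_outlier():
    rng = np.random.default_rng(7)
    obs = rng.gamma(10, 1, 21)
    pred = obs + rng.normal(0, 0.01, 21)
    pred[7] = obs[7] + 50.0
    res = ad.compare_predicted_observed(pred, obs)
    assert res.residuals["outlier"].iloc[7]
    assert res.residuals["outlier"].sum() == 1


def test_compare_requires_five_pairs():
    with pytest.raises(ValueError, match=">= 5"):
        ad.compare_predicted_observed([1, 2], [1, 2])


def test_compare_respects_stable_mask():
    obs = np.arange(1.0, 13.0)
    pred = obs.copy()
    pred[-2:] += 100
    mask = np.ones(12, bool)
    mask[-2:] = False
    res = ad.compare_predicted_observed(pred, obs, stable_mask=mask)
    assert res.degenerate
    assert len(res.residuals) == 10


# ----------------------------------------------- selected model extraction

def test_selected_model_predicts_posterior_mean(small_fit):
    """Keeping every group reproduces the posterior-mean linear predictor."""
    cohort, design, samples = small_fit
    y = cohort.dose.to_numpy()
    model = ad.extract_selected_model(samples, y,
                                      included_groups=[g.index for g in design.groups])
    eta = model.predict_ln_dose(design.X_cov, design.X_terms)
    np.testing.assert_allclose(eta, samples.posterior_mean_eta(), atol=1e-12)
    assert np.isfinite(model.dic)
    assert 0 <= model.variance_explained <= 100
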