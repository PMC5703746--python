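"""Bayesian variable-selection gamma GLM for anticoagulant dose.

The model: dose y_i ~ Gamma(shape tau, rate tau / mu_i) with
log mu_i = c + sum_i alpha_i x_i + sum_j I_j (beta_{1,j} v_{1,j} + beta_{2,j} v_{2,j})
          + sum over within-gene pairs of I_{j,k} times the four diplotype terms.

Priors: tau ~ Gamma(lambda, kappa); c ~ Normal(0, tau_mu^2);
alpha_i ~ Normal(0, tau_alpha^2); each beta ~ Laplace(0, tau_beta) (the
slab); each inclusion indicator ~ Bernoulli(pi) with pi ~ Uniform(a, b)
(the spike: a term is exactly removed when its indicator is 0).

Fitting is Metropolis-within-Gibbs (see ``_sampler``), run as several
independent chains whose convergence is checked with the classic
Gelman-Rubin potential scale reduction factor (threshold 1.2).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special

from ._sampler import run_chain
from .design import DesignMatrix

log = logging.getLogger("acenodose")

GELMAN_RUBIN_THRESHOLD = 1.2
# marginal beta draws are spike/slab mixtures; R-hat is only meaningful for
# effects that are essentially always in the model
DIAGNOSTIC_PIP = 0.9


@dataclass(frozen=True)
class ModelSpec:
    """Prior hyperparameters (the published protocol states none; these are
    the package defaults: vague on tau and the intercept/covariates, a
    unit-scale regularizing slab, and a sparsity-encoding inclusion prior)."""

    lam: float = 0.01          # tau ~ Gamma(lam, kap): shape
    kap: float = 0.01          # rate
    tau_mu2: float = 100.0     # intercept prior variance
    tau_alpha2: float = 100.0  # covariate prior variance
    tau_beta: float = 1.0      # Laplace slab scale
    a: float = 0.001           # pi ~ Uniform(a, b)
    b: float = 0.1

    def __post_init__(self) -> None:
        if not (0 <= self.a < self.b <= 1):
            raise ValueError("need 0 <= a < b <= 1 for the pi prior")
        for name in ("lam", "kap", "tau_mu2", "tau_alpha2", "tau_beta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"prior scale {name} must be positive")

    @property
    def prior_inclusion(self) -> float:
        """Prior-predictive inclusion probability E[pi] = (a+b)/2."""
        return (self.a + self.b) / 2.0


@dataclass(frozen=True)
class McmcSettings:
    n_chains: int = 5
    n_iterations: int = 110_000
    n_burnin: int = 10_000
    thinning: int = 10
    seed: int = 0
    init: str = "random"       # "random" | "zeros"

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iterations:
            raise ValueError("n_burnin must be < n_iterations")
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")
        if self.init not in ("random", "zeros"):
            raise ValueError("init must be 'random' or 'zeros'")

    @classmethod
    def scaled_down(cls, seed: int = 0, **kw) -> "McmcSettings":
        """Desk-scale protocol: 5 chains x 11,000 iterations, 1,000 burn-in."""
        return cls(n_chains=5, n_iterations=11_000, n_burnin=1_000,
                   thinning=10, seed=seed, **kw)

    @property
    def n_retained(self) -> int:
        return (self.n_iterations - self.n_burnin) // self.thinning


def log_likelihood(dose: np.ndarray, linear_predictor: np.ndarray, tau: float) -> float:
    """Gamma log-likelihood with mean exp(linear_predictor) and shape tau."""
    y = np.asarray(dose, dtype=float)
    eta = np.asarray(linear_predictor, dtype=float)
    if (y <= 0).any():
        raise ValueError("doses must be positive")
    bad = np.flatnonzero(~np.isfinite(eta))
    if bad.size:
        raise ValueError(f"non-finite linear predictor for sample index {bad[0]}")
    return float(
        np.sum((tau - 1) * np.log(y) + tau * (np.log(tau) - eta)
               - special.gammaln(tau) - tau * y * np.exp(-eta))
    )


def gelman_rubin(chain_draws: np.ndarray) -> float:
    """Classic potential scale reduction factor.

    ``chain_draws`` is (n_chains, n_draws).  Returns nan (flagged undefined)
    when every chain has zero internal variance.
    """
    x = np.asarray(chain_draws, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 10:
        raise ValueError("need >= 2 chains with >= 10 draws each")
    m, s = x.shape
    within = x.var(axis=1, ddof=1).mean()
    if within == 0:
        log.warning("Gelman-Rubin undefined: zero within-chain variance")
        return float("nan")
    between = s * x.mean(axis=1).var(ddof=1)
    var_hat = (s - 1) / s * within + between / s
    return float(np.sqrt(var_hat / within))


def hdi(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``mass`` of the draws."""
    if not (0 < mass < 1):
        raise ValueError("mass must be in (0, 1)")
    x = np.sort(np.asarray(draws, dtype=float))
    n = x.size
    k = int(math.ceil(mass * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k])


@dataclass
class PosteriorSamples:
    """Retained draws from all chains, plus diagnostics.

    Arrays have leading axes (n_chains, n_draws); ``inc`` is indexed by
    indicator group, ``beta`` by design column (zero when excluded).
    """

    design: DesignMatrix
    spec: ModelSpec
    settings: McmcSettings
    c: np.ndarray              # (C, S)
    alpha: np.ndarray          # (C, S, m)
    beta: np.ndarray           # (C, S, p)
    inc: np.ndarray            # (C, S, G) int8
    pi: np.ndarray             # (C, S)
    tau: np.ndarray            # (C, S)
    converged: bool = True
    rhat: dict = field(default_factory=dict)

    # ----------------------------------------------------------- summaries
    def group_pip(self) -> np.ndarray:
        """Posterior inclusion probability per indicator group."""
        return self.inc.reshape(self.inc.shape[0] * self.inc.shape[1], self.inc.shape[2]).mean(axis=0)

    def column_pip(self) -> np.ndarray:
        """Per-column PIP (nonzero beta fraction; equals its group's PIP)."""
        return (self.beta.reshape(self.beta.shape[0] * self.beta.shape[1], self.beta.shape[2]) != 0).mean(axis=0)

    def snp_pip(self) -> dict[str, float]:
        """Per-SNP PIP: max over the SNP's genotype-dummy columns."""
        pips = self.column_pip()
        out: dict[str, float] = {}
        for t in self.design.terms:
            if t.kind == "main":
                vid = t.variants[0]
                out[vid] = max(out.get(vid, 0.0), float(pips[t.column]))
        return out

    def beta_flat(self) -> np.ndarray:
        return self.beta.reshape(self.beta.shape[0] * self.beta.shape[1], self.beta.shape[2])

    def conditional_beta(self, column: int) -> np.ndarray:
        """Slab draws of one effect (conditional on inclusion)."""
        flat = self.beta_flat()[:, column]
        return flat[flat != 0]

    def posterior_mean_eta(self) -> np.ndarray:
        """Posterior-mean linear predictor per sample."""
        c_bar = self.c.mean()
        alpha_bar = self.alpha.reshape(self.alpha.shape[0] * self.alpha.shape[1], self.alpha.shape[2]).mean(axis=0)
        beta_bar = self.beta_flat().mean(axis=0)
        return (c_bar + self.design.X_cov @ alpha_bar
                + self.design.X_terms @ beta_bar)

    def parameter_means(self) -> dict:
        return {
            "c": float(self.c.mean()),
            "alpha": self.alpha.reshape(self.alpha.shape[0] * self.alpha.shape[1], self.alpha.shape[2]).mean(axis=0),
            "beta": self.beta_flat().mean(axis=0),
            "tau": float(self.tau.mean()),
            "pi": float(self.pi.mean()),
        }

    # --------------------------------------------------------- diagnostics
    def compute_rhat(self) -> dict:
        """R-hat for the always-present parameters and high-PIP effects."""
        out: dict[str, float] = {"c": gelman_rubin(self.c),
                                 "tau": gelman_rubin(np.log(self.tau)),
                                 "pi": gelman_rubin(self.pi)}
        for j, name in enumerate(self.design.covariate_names):
            out[f"alpha[{name}]"] = gelman_rubin(self.alpha[:, :, j])
        pips = self.column_pip()
        for t in self.design.terms:
            if pips[t.column] >= DIAGNOSTIC_PIP:
                out[f"beta[{t.label}]"] = gelman_rubin(self.beta[:, :, t.column])
        self.rhat = out
        finite = [v for v in out.values() if np.isfinite(v)]
        self.converged = bool(finite) and max(finite) < GELMAN_RUBIN_THRESHOLD
        return out

    # --------------------------------------------------------- persistence
    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        C = self.c.shape[0]
        cols = (["c"] + [f"alpha[{n}]" for n in self.design.covariate_names]
                + [f"beta[{t.label}]" for t in self.design.terms]
                + [f"inc[{g.index}]" for g in self.design.groups]
                + ["pi", "tau"])
        for ch in range(C):
            block = np.hstack([
                self.c[ch][:, None], self.alpha[ch], self.beta[ch],
                self.inc[ch].astype(float), self.pi[ch][:, None],
                self.tau[ch][:, None],
            ])
            pd.DataFrame(block, columns=cols).to_csv(out / f"chain{ch}.csv", index=False)
        manifest = {
            "n_chains": C,
            "settings": asdict(self.settings),
            "spec": asdict(self.spec),
            "converged": self.converged,
            "rhat": {k: (None if not np.isfinite(v) else v) for k, v in self.rhat.items()},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)


def _sparse_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ptr = [0]
    idx: list[int] = []
    val: list[float] = []
    for j in range(X.shape[1]):
        nz = np.flatnonzero(X[:, j] != 0)
        idx.extend(nz.tolist())
        val.extend(X[nz, j].tolist())
        ptr.append(len(idx))
    return (np.asarray(ptr, dtype=np.int64),
            np.asarray(idx, dtype=np.int64),
            np.asarray(val, dtype=np.float64))


def _addmove_proposal(
    Xc: np.ndarray, Xt: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Data-informed centre/scale for the indicator add move.

    Per term column, the univariate least-squares slope of the
    covariate-adjusted log dose; the add proposal mixes the Laplace slab
    prior with a normal at this centre (the acceptance ratio carries the
    exact density correction, so this only affects mixing, not the target).
    """
    logy = np.log(y)
    Z = np.hstack([np.ones((Xc.shape[0], 1)), Xc])
    resid = logy - Z @ np.linalg.lstsq(Z, logy, rcond=None)[0]
    sigma = resid.std(ddof=Z.shape[1]) if resid.size > Z.shape[1] else resid.std()
    p = Xt.shape[1]
    mean = np.zeros(p)
    sd = np.full(p, 0.5)
    for j in range(p):
        x = Xt[:, j] - Xt[:, j].mean()
        ss = float(x @ x)
        if ss > 0:
            mean[j] = float(x @ resid / ss)
            sd[j] = float(np.sqrt((sigma**2) / ss + 0.05**2))
    return mean, sd


def _related_groups(design: DesignMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Group pairs eligible for swap moves: every interaction group with
    the main-effect group of each of its variants.  These near-collinear
    explanations are the multimodality the swap move addresses."""
    main_of = {g.variants[0]: g.index for g in design.groups if g.kind == "snp"}
    a, b = [], []
    for g in design.groups:
        if g.kind != "pair":
            continue
        for vid in g.variants:
            if vid in main_of:
                a.append(main_of[vid])
                b.append(g.index)
    return np.asarray(a, dtype=np.int64), np.asarray(b, dtype=np.int64)


def _chain_seed(base: int, chain: int) -> int:
    return int((base * 1_000_003 + 7919 * (chain + 1)) % 2_147_483_647) or 1


def fit_mcmc(
    design: DesignMatrix,
    dose: np.ndarray | pd.Series,
    spec: ModelSpec | None = None,
    settings: McmcSettings | None = None,
    likelihood_on: bool = True,
) -> PosteriorSamples:
    """Run the Metropolis-within-Gibbs sampler over independent chains.

    ``likelihood_on=False`` samples the prior through the identical kernel
    (used by the prior-recovery checks).  Non-convergence (any finite R-hat
    at or above 1.2) is flagged and logged, never silent.
    """
    spec = spec or ModelSpec()
    settings = settings or McmcSettings()
    y = np.asarray(dose, dtype=float)
    if y.shape[0] != design.n_samples:
        raise ValueError("dose and design are not aligned")
    if (y <= 0).any() or not np.isfinite(y).all():
        raise ValueError("doses must be positive and finite")
    if design.n_term_columns + design.X_cov.shape[1] == 0:
        raise ValueError("design has no terms")

    Xc = np.ascontiguousarray(design.X_cov, dtype=np.float64)
    col_ptr, row_idx, val = _sparse_columns(design.X_terms)
    prop_mean, prop_sd = _addmove_proposal(Xc, design.X_terms, y)
    col_mean = design.X_terms.mean(axis=0) if design.n_term_columns else np.empty(0)
    rel_a, rel_b = _related_groups(design)
    grp_ptr = [0]
    order: list[int] = []
    for g in design.groups:
        order.extend(g.columns)
        grp_ptr.append(len(order))
    # kernel expects group columns contiguous; build_design guarantees the
    # natural column order already satisfies this
    assert order == list(range(design.n_term_columns))
    grp_ptr = np.asarray(grp_ptr, dtype=np.int64)

    m = Xc.shape[1]
    p = design.n_term_columns
    G = len(design.groups)
    S = settings.n_retained

    c_all = np.empty((settings.n_chains, S))
    alpha_all = np.empty((settings.n_chains, S, m))
    beta_all = np.empty((settings.n_chains, S, p))
    inc_all = np.empty((settings.n_chains, S, G), dtype=np.int8)
    pi_all = np.empty((settings.n_chains, S))
    tau_all = np.empty((settings.n_chains, S))

    for ch in range(settings.n_chains):
        seed = _chain_seed(settings.seed, ch)
        rng = np.random.default_rng(seed)
        if settings.init == "random":
            c0 = float(np.log(y.mean()) + rng.normal(0, 1.0))
            alpha0 = rng.normal(0, 0.3, size=m)
            pi0 = float(rng.uniform(spec.a, spec.b))
            tau0 = float(np.exp(rng.normal(0.5, 0.8)))
            inc0 = (rng.random(G) < pi0).astype(np.int8)
            beta0 = np.zeros(p)
            for g in design.groups:
                if inc0[g.index]:
                    beta0[list(g.columns)] = rng.laplace(0, spec.tau_beta, size=len(g.columns))
        else:
            c0, alpha0 = 0.0, np.zeros(m)
            pi0 = spec.prior_inclusion
            tau0 = 1.0
            inc0 = np.zeros(G, dtype=np.int8)
            beta0 = np.zeros(p)
        out = run_chain(
            y, Xc, col_ptr, row_idx, val, grp_ptr,
            prop_mean, prop_sd, col_mean, rel_a, rel_b,
            settings.n_iterations, settings.n_burnin, settings.thinning,
            seed,
            spec.tau_mu2, spec.tau_alpha2, spec.tau_beta, spec.lam, spec.kap,
            spec.a, spec.b,
            c0, alpha0, beta0, inc0, pi0, tau0,
            likelihood_on,
        )
        c_all[ch], alpha_all[ch], beta_all[ch], inc_all[ch], pi_all[ch], tau_all[ch] = out

    samples = PosteriorSamples(
        design=design, spec=spec, settings=settings,
        c=c_all, alpha=alpha_all, beta=beta_all, inc=inc_all,
        pi=pi_all, tau=tau_all,
    )
    samples.compute_rhat()
    if not samples.converged:
        worst = max((v for v in samples.rhat.values() if np.isfinite(v)), default=float("nan"))
        log.warning("MCMC convergence flag FALSE: max R-hat = %.3f", worst)
    return samples


def summarize_posterior(
    samples: PosteriorSamples,
    prior_inclusion: float | None = None,
    mass: float = 0.95,
) -> pd.DataFrame:
    """Posterior report: per term the genotype label, posterior mean
    (standardized and natural units), HDI, PIP and inclusion Bayes factor,
    sorted by PIP descending (covariates and intercept listed first)."""
    from .selection import bayes_factor_from_pip, format_bayes_factor

    if prior_inclusion is None:
        prior_inclusion = samples.spec.prior_inclusion
    design = samples.design
    rows = []
    c_flat = samples.c.ravel()
    lo, hi = hdi(c_flat, mass)
    rows.append({
        "term": "intercept", "gene": "", "pip": 1.0, "mean": float(c_flat.mean()),
        "mean_natural": float(c_flat.mean()), "hdi_low": lo, "hdi_high": hi,
        "bayes_factor": float("inf"),
    })
    alpha_flat = samples.alpha.reshape(samples.alpha.shape[0] * samples.alpha.shape[1], samples.alpha.shape[2])
    for j, name in enumerate(design.covariate_names):
        d = alpha_flat[:, j]
        lo, hi = hdi(d, mass)
        rows.append({
            "term": name, "gene": "", "pip": 1.0, "mean": float(d.mean()),
            "mean_natural": design.natural_covariate_coef(name, float(d.mean())),
            "hdi_low": lo, "hdi_high": hi, "bayes_factor": float("inf"),
        })
    pips = samples.column_pip()
    for t in design.terms:
        cond = samples.conditional_beta(t.column)
        if cond.size >= 10:
            mean = float(cond.mean())
            lo, hi = hdi(cond, mass)
        else:
            mean, lo, hi = 0.0, 0.0, 0.0
        pip = float(pips[t.column])
        rows.append({
            "term": t.label, "gene": t.gene, "pip": pip, "mean": mean,
            "mean_natural": mean,   # dummy-coded genotype terms are already natural
            "hdi_low": lo, "hdi_high": hi,
            "bayes_factor": bayes_factor_from_pip(pip, prior_inclusion),
        })
    df = pd.DataFrame(rows)
    head = df.iloc[: 1 + len(design.covariate_names)]
    tail = df.iloc[1 + len(design.covariate_names):].sort_values("pip", ascending=False)
    out = pd.concat([head, tail]).reset_index(drop=True)
    out["bayes_factor_report"] = [format_bayes_factor(b) for b in out["bayes_factor"]]
    return out
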