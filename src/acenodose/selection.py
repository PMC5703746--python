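"""Model selection: inclusion Bayes factors, the conditioned decision tree,
DIC comparison, final-model extraction and variance explained.

The Bayes factor for a term is Savage-Dickey-style for its indicator:
posterior inclusion odds (within the subset of MCMC draws satisfying the
conditioning states on the path) divided by the prior inclusion odds
implied by the Uniform(a, b) prior on pi.  Tree growth is greedy in PIP
order; a branch keeps a term only when its conditioned Bayes factor clears
the cutoff c_j = 3 + m_j, m_j counting the terms conditioned absent on the
path (3 being the Jeffreys "substantial evidence" floor).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignMatrix
from .glm import PosteriorSamples, hdi, log_likelihood

log = logging.getLogger("acenodose")

BF_REPORT_CAP = 900.0
MIN_CONDITIONED_DRAWS = 200
CUTOFF_BASE = 3.0


def bayes_factor_from_pip(pip: float, prior_inclusion: float) -> float:
    """(q/(1-q)) / (p/(1-p)); infinite when the posterior never excludes."""
    if not (0 < prior_inclusion < 1):
        raise ValueError("prior inclusion probability must be in (0, 1)")
    prior_odds = prior_inclusion / (1 - prior_inclusion)
    if pip >= 1.0:
        return float("inf")
    return (pip / (1 - pip)) / prior_odds


def format_bayes_factor(bf: float, cap: float = BF_REPORT_CAP) -> str:
    return f">{cap:.0f}" if bf > cap else f"{bf:.2f}"


def _conditioned_mask(samples: PosteriorSamples, conditioning) -> np.ndarray:
    inc = samples.inc.reshape(samples.inc.shape[0] * samples.inc.shape[1], samples.inc.shape[2])
    mask = np.ones(inc.shape[0], dtype=bool)
    for group, state in conditioning:
        mask &= inc[:, group] == state
    return mask


def bayes_factor_inclusion(
    samples: PosteriorSamples,
    group: int,
    conditioning: tuple[tuple[int, int], ...] = (),
    min_draws: int = MIN_CONDITIONED_DRAWS,
) -> float:
    """Inclusion Bayes factor of an indicator group, conditioned on the
    inclusion states of other groups.

    Raises when fewer than ``min_draws`` MCMC draws satisfy the
    conditioning (the remedy is longer chains).
    """
    mask = _conditioned_mask(samples, conditioning)
    if mask.sum() < min_draws:
        raise ValueError(
            f"only {int(mask.sum())} draws satisfy the conditioning "
            f"(need >= {min_draws}); run longer chains"
        )
    inc = samples.inc.reshape(samples.inc.shape[0] * samples.inc.shape[1], samples.inc.shape[2])
    q = float(inc[mask, group].mean())
    return bayes_factor_from_pip(q, samples.spec.prior_inclusion)


# --------------------------------------------------------------- the tree

@dataclass
class TreeNode:
    group: int
    label: str
    parent_state: int | None      # inclusion state of the parent branch (None at root)
    bayes_factor: float
    cutoff: float
    children: list["TreeNode"] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "label": self.label,
            "parent_state": self.parent_state,
            "bayes_factor": None if np.isinf(self.bayes_factor) else self.bayes_factor,
            "bayes_factor_report": format_bayes_factor(self.bayes_factor),
            "cutoff": self.cutoff,
            "children": [c.to_dict() for c in self.children],
        }


@dataclass
class DecisionTree:
    root: TreeNode | None
    cutoff_base: float = CUTOFF_BASE

    def retained_groups(self) -> list[int]:
        """Groups on solid (included) paths from the root."""
        out: list[int] = []

        def walk(node: TreeNode) -> None:
            out.append(node.group)
            for child in node.children:
                if child.parent_state == 1:
                    walk(child)
        if self.root is not None:
            walk(self.root)
        return sorted(set(out))

    def to_json(self) -> str:
        return json.dumps(
            {"cutoff_base": self.cutoff_base,
             "root": None if self.root is None else self.root.to_dict()},
            indent=2,
        )

    def render(self) -> str:
        lines: list[str] = []

        def walk(node: TreeNode, depth: int) -> None:
            edge = ""
            if node.parent_state is not None:
                edge = "--- " if node.parent_state == 1 else "- - "
            lines.append(
                "  " * depth + edge
                + f"{node.label}  BF={format_bayes_factor(node.bayes_factor)}"
                + f" (cutoff {node.cutoff:g})"
            )
            for child in node.children:
                walk(child, depth + 1)
        if self.root is None:
            return "(empty tree)"
        walk(self.root, 0)
        return "\n".join(lines)

    def to_dot(self) -> str:
        lines = ["digraph decision_tree {"]

        def walk(node: TreeNode, uid: str) -> None:
            lines.append(f'  "{uid}" [label="{node.label}\\nBF {format_bayes_factor(node.bayes_factor)}"];')
            for i, child in enumerate(node.children):
                cid = f"{uid}.{i}"
                style = "solid" if child.parent_state == 1 else "dashed"
                lines.append(f'  "{uid}" -> "{cid}" [style={style}];')
                walk(child, cid)
        if self.root is not None:
            walk(self.root, "root")
        lines.append("}")
        return "\n".join(lines)


def cutoff(m_absent: int, base: float = CUTOFF_BASE) -> float:
    """The branch-retention cutoff c_j = base + m_j."""
    return base + m_absent


def build_decision_tree(
    samples: PosteriorSamples,
    cutoff_base: float = CUTOFF_BASE,
    max_terms: int = 10,
    min_draws: int = MIN_CONDITIONED_DRAWS,
    never_condition: tuple[str, ...] = (),
    max_depth: int = 4,
) -> DecisionTree:
    """Greedy PIP-ordered tree with both included (solid) and excluded
    (dashed) branches.

    ``never_condition`` names genes/labels that may appear as nodes but are
    not branched on (the high-dose-outlier convention).
    """
    pips = samples.group_pip()
    order = np.argsort(-pips)[:max_terms]
    labels = {g.index: f"{g.gene}:{'+'.join(g.variants)}" for g in samples.design.groups}
    genes = {g.index: g.gene for g in samples.design.groups}

    def first_retained(candidates, path):
        m_absent = sum(1 for _, state in path if state == 0)
        cut = cutoff(m_absent, cutoff_base)
        for i, g in enumerate(candidates):
            try:
                bf = bayes_factor_inclusion(samples, int(g), tuple(path), min_draws)
            except ValueError:
                log.info("tree branch starved of draws at %s; stopping", labels[int(g)])
                return None
            if bf >= cut:
                return i, int(g), bf, cut
        return None

    def grow(candidates, path, parent_state, depth):
        hit = first_retained(candidates, path)
        if hit is None:
            return None
        i, g, bf, cut = hit
        node = TreeNode(g, labels[g], parent_state, bf, cut)
        rest = [c for k, c in enumerate(candidates) if k != i]
        if depth < max_depth and rest:
            blocked = genes[g] in never_condition or labels[g] in never_condition
            states = () if blocked else (1, 0)
            for state in states:
                child = grow(rest, path + [(g, state)], state, depth + 1)
                if child is not None:
                    node.children.append(child)
        return node

    root = grow(list(order), [], None, 0)
    return DecisionTree(root, cutoff_base)


# ------------------------------------------------------------------- DIC

def dic(
    samples: PosteriorSamples,
    design: DesignMatrix | None = None,
    dose: np.ndarray | pd.Series | None = None,
    max_draws: int = 400,
) -> float:
    """Deviance information criterion D-bar + p_D.

    D-bar is the mean deviance over (an evenly spaced subset of) the
    retained draws; p_D = D-bar - D(posterior means).
    """
    design = design or samples.design
    if dose is None:
        raise ValueError("dose vector required")
    y = np.asarray(dose, dtype=float)
    c = samples.c.ravel()
    A = samples.alpha.reshape(samples.alpha.shape[0] * samples.alpha.shape[1], samples.alpha.shape[2])
    B = samples.beta_flat()
    T = samples.tau.ravel()
    n_draws = c.shape[0]
    sel = np.linspace(0, n_draws - 1, min(max_draws, n_draws)).astype(int)
    etas = c[sel, None] + A[sel] @ design.X_cov.T + B[sel] @ design.X_terms.T
    devs = np.array([-2.0 * log_likelihood(y, etas[k], T[s])
                     for k, s in enumerate(sel)])
    d_bar = float(devs.mean())
    means = samples.parameter_means()
    eta_bar = means["c"] + design.X_cov @ means["alpha"] + design.X_terms @ means["beta"]
    d_at_mean = -2.0 * log_likelihood(y, eta_bar, means["tau"])
    if not np.isfinite(d_at_mean):
        raise ValueError("deviance at the posterior mean is not finite")
    p_d = d_bar - d_at_mean
    return d_bar + p_d


def fit_submodel(
    design: DesignMatrix,
    dose: np.ndarray | pd.Series,
    group_indices,
    settings=None,
    spec=None,
):
    """Refit with only the given groups, inclusion prior pinned near 1.

    Used for DIC comparisons between fixed term sets: the DIC of a
    spike-and-slab fit is not attributable to one submodel, so candidate
    models are refitted with their terms effectively always included.
    """
    from .glm import McmcSettings, ModelSpec, fit_mcmc

    spec = spec or ModelSpec()
    pinned = ModelSpec(lam=spec.lam, kap=spec.kap, tau_mu2=spec.tau_mu2,
                       tau_alpha2=spec.tau_alpha2, tau_beta=spec.tau_beta,
                       a=0.98, b=0.999)
    sub = design.subset_groups(group_indices)
    settings = settings or McmcSettings.scaled_down()
    return fit_mcmc(sub, dose, pinned, settings), sub


def dic_for_groups(
    design: DesignMatrix,
    dose: np.ndarray | pd.Series,
    group_indices,
    settings=None,
    spec=None,
) -> float:
    samples, sub = fit_submodel(design, dose, group_indices, settings, spec)
    return dic(samples, sub, dose)


# ------------------------------------------------- selected-model surface

@dataclass
class SelectedModel:
    """A final model: retained groups with posterior-mean coefficients."""

    included_groups: list[int]
    coefficients: pd.DataFrame      # term-level table (means, HDIs, natural units)
    intercept: float                # standardized-scale intercept
    alpha: np.ndarray
    beta: np.ndarray                # marginal posterior means, zeroed off-model
    tau: float
    dic: float
    variance_explained: float
    design: DesignMatrix

    def predict_ln_dose(self, X_cov: np.ndarray, X_terms: np.ndarray) -> np.ndarray:
        return self.intercept + X_cov @ self.alpha + X_terms @ self.beta


def variance_explained(
    predicted_ln_dose: np.ndarray,
    observed_dose: np.ndarray,
    method: str = "corr",
) -> float:
    """Percent of log-dose variation captured by the predictions.

    ``corr``: 100 * squared Pearson correlation between observed log dose
    and predicted log dose.  ``deviance``: 100 * (1 - residual/null squared
    error of log dose), reported side by side in the model report.
    """
    pred = np.asarray(predicted_ln_dose, dtype=float)
    logy = np.log(np.asarray(observed_dose, dtype=float))
    if pred.std() == 0:
        log.warning("variance_explained: predictions are constant; returning 0")
        return 0.0
    if method == "corr":
        r = np.corrcoef(logy, pred)[0, 1]
        return float(100.0 * r * r)
    if method == "deviance":
        ss_res = float(((logy - pred) ** 2).sum())
        ss_tot = float(((logy - logy.mean()) ** 2).sum())
        return float(100.0 * max(0.0, 1.0 - ss_res / ss_tot))
    raise ValueError(f"unknown method {method!r}")


def extract_selected_model(
    samples: PosteriorSamples,
    dose: np.ndarray | pd.Series,
    included_groups: list[int] | None = None,
    pip_threshold: float = 0.5,
) -> SelectedModel:
    """Freeze a model: keep the given groups (default: PIP >= threshold),
    zero out the rest, attach DIC and variance explained."""
    design = samples.design
    y = np.asarray(dose, dtype=float)
    if included_groups is None:
        pips = samples.group_pip()
        included_groups = [g.index for g in design.groups if pips[g.index] >= pip_threshold]
    keep_cols = set()
    for g in design.groups:
        if g.index in included_groups:
            keep_cols.update(g.columns)
    means = samples.parameter_means()
    beta = means["beta"].copy()
    for j in range(beta.shape[0]):
        if j not in keep_cols:
            beta[j] = 0.0
    eta = means["c"] + design.X_cov @ means["alpha"] + design.X_terms @ beta
    ve = variance_explained(eta, y)
    rows = [{"term": "intercept", "mean": means["c"], "mean_natural": _natural_intercept(design, means),
             "hdi_low": hdi(samples.c.ravel())[0], "hdi_high": hdi(samples.c.ravel())[1]}]
    alpha_flat = samples.alpha.reshape(samples.alpha.shape[0] * samples.alpha.shape[1], samples.alpha.shape[2])
    for j, name in enumerate(design.covariate_names):
        lo, hi_ = hdi(alpha_flat[:, j])
        rows.append({"term": name, "mean": float(means["alpha"][j]),
                     "mean_natural": design.natural_covariate_coef(name, float(means["alpha"][j])),
                     "hdi_low": lo, "hdi_high": hi_})
    for t in design.terms:
        if t.column in keep_cols:
            cond = samples.conditional_beta(t.column)
            lo, hi_ = hdi(cond) if cond.size >= 10 else (0.0, 0.0)
            rows.append({"term": t.label, "mean": float(beta[t.column]),
                         "mean_natural": float(beta[t.column]),
                         "hdi_low": lo, "hdi_high": hi_})
    model = SelectedModel(
        included_groups=sorted(included_groups),
        coefficients=pd.DataFrame(rows),
        intercept=means["c"],
        alpha=means["alpha"],
        beta=beta,
        tau=means["tau"],
        dic=dic(samples, design, y),
        variance_explained=ve,
        design=design,
    )
    return model


def _natural_intercept(design: DesignMatrix, means: dict) -> float:
    shift = 0.0
    for j in range(len(design.covariate_names)):
        shift += means["alpha"][j] * design.cov_means[j] / design.cov_sds[j]
    return float(means["c"] - shift)


# ------------------------------------- predicted vs observed dose checking

@dataclass
class PredictionComparison:
    p_value: float
    test: str
    degenerate: bool
    residuals: pd.DataFrame


def compare_predicted_observed(
    predicted: np.ndarray | pd.Series,
    observed: np.ndarray | pd.Series,
    stable_mask: np.ndarray | None = None,
    test: str = "wilcoxon",
    samples: list[str] | None = None,
) -> PredictionComparison:
    """Paired two-sided test of predicted vs observed dose among INR-stable
    samples, plus a per-sample residual table flagging gross outliers."""
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if stable_mask is not None:
        stable_mask = np.asarray(stable_mask, dtype=bool)
        pred, obs = pred[stable_mask], obs[stable_mask]
        if samples is not None:
            samples = [s for s, keep in zip(samples, stable_mask) if keep]
    if pred.shape[0] < 5:
        raise ValueError("need >= 5 paired values")
    diffs = pred - obs
    degenerate = bool(np.allclose(diffs, 0))
    if degenerate:
        p = 1.0
    elif test == "wilcoxon":
        p = float(stats.wilcoxon(pred, obs, zero_method="wilcox").pvalue)
    elif test == "ttest":
        p = float(stats.ttest_rel(pred, obs).pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    mad = np.median(np.abs(diffs - np.median(diffs)))
    scale = 1.4826 * mad if mad > 0 else (diffs.std() or 1.0)
    z = (diffs - np.median(diffs)) / scale
    table = pd.DataFrame({
        "predicted": pred,
        "observed": obs,
        "residual": diffs,
        "outlier": np.abs(z) > 3.0,
    }, index=samples if samples is not None else range(len(pred)))
    return PredictionComparison(p, test, degenerate, table)
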