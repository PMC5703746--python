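"""Design construction for the Bayesian dose model.

Each retained SNP j contributes two dummy columns: v1_j (heterozygote
indicator) and v2_j (homozygous-alt indicator), so genotype 0 -> (0,0),
1 -> (1,0), 2 -> (0,1).  Every qualifying within-gene pair contributes the
four products v_{r1,j} * v_{r2,k} for r1, r2 in {1,2}.  Continuous clinical
covariates are standardized to mean zero / unit sample variance (divisor
n-1) with the constants stored so fitted coefficients can be mapped back to
natural units; sex stays a 0/1 male indicator by default.

Frequency filters follow the published protocol: main effects require
alt-allele frequency strictly inside (0.05, 0.95), interactions strictly
inside (0.10, 0.90).  "Frequency" is read as alt-allele frequency with
strict inequalities (configurable), and exclusions are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort

log = logging.getLogger("acenodose")

MAIN_FREQ_BOUNDS = (0.05, 0.95)
PAIR_FREQ_BOUNDS = (0.10, 0.90)
DEFAULT_MISSING_THRESHOLD = 0.10


@dataclass(frozen=True)
class Term:
    """Registry entry mapping one design column to its biological meaning."""

    column: int
    kind: str                      # "covariate" | "main" | "interaction"
    variants: tuple[str, ...]      # () for covariates
    classes: tuple[int, ...]       # genotype class per variant (1 het, 2 hom-alt)
    gene: str
    label: str
    group: int                     # indicator-group index; -1 for covariates


@dataclass(frozen=True)
class TermGroup:
    """Columns sharing one inclusion indicator: a SNP (2) or a pair (4)."""

    index: int
    kind: str                      # "snp" | "pair"
    variants: tuple[str, ...]
    gene: str
    columns: tuple[int, ...]


@dataclass
class DesignMatrix:
    samples: list[str]
    covariate_names: list[str]
    X_cov: np.ndarray              # (n, m) standardized covariates
    cov_means: np.ndarray
    cov_sds: np.ndarray            # 1.0 for columns left unstandardized
    X_terms: np.ndarray            # (n, p) genotype-term columns
    terms: list[Term]
    groups: list[TermGroup]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_term_columns(self) -> int:
        return self.X_terms.shape[1]

    def term_for_column(self, column: int) -> Term:
        return self.terms[column]

    def natural_covariate_coef(self, name: str, standardized_coef: float) -> float:
        """Back-transform a standardized covariate effect to natural units."""
        j = self.covariate_names.index(name)
        return standardized_coef / self.cov_sds[j]

    def subset_groups(self, group_indices) -> "DesignMatrix":
        """A design containing only the given indicator groups (covariates
        always kept), with columns and groups renumbered."""
        keep = [g for g in self.groups if g.index in set(group_indices)]
        col_map: dict[int, int] = {}
        new_cols, new_terms, new_groups = [], [], []
        for gi, g in enumerate(keep):
            cols = []
            for c in g.columns:
                col_map[c] = len(new_cols)
                new_cols.append(self.X_terms[:, c])
                t = self.terms[c]
                new_terms.append(Term(col_map[c], t.kind, t.variants, t.classes,
                                      t.gene, t.label, gi))
                cols.append(col_map[c])
            new_groups.append(TermGroup(gi, g.kind, g.variants, g.gene, tuple(cols)))
        X = np.column_stack(new_cols) if new_cols else np.empty((self.n_samples, 0))
        return DesignMatrix(
            samples=list(self.samples),
            covariate_names=list(self.covariate_names),
            X_cov=self.X_cov,
            cov_means=self.cov_means,
            cov_sds=self.cov_sds,
            X_terms=X,
            terms=new_terms,
            groups=new_groups,
        )

    def export(self, path) -> None:
        """Audit export: registry header lines then the full matrix as TSV."""
        with open(path, "w") as fh:
            for t in self.terms:
                fh.write(
                    f"# term\tcol={t.column}\tkind={t.kind}\tgene={t.gene}"
                    f"\tvariants={','.join(t.variants)}"
                    f"\tclasses={','.join(map(str, t.classes))}\tgroup={t.group}\n"
                )
            full = np.hstack([self.X_cov, self.X_terms])
            cols = self.covariate_names + [t.label for t in self.terms]
            pd.DataFrame(full, index=self.samples, columns=cols).to_csv(fh, sep="\t")


@dataclass
class FilterResult:
    retained: list[str]
    exclusions: pd.DataFrame = field(default_factory=pd.DataFrame)


def _alt_freqs(cohort: Cohort) -> pd.Series:
    g = cohort.genotypes
    with np.errstate(invalid="ignore"):
        freqs = np.nansum(g, axis=0) / (2.0 * (~np.isnan(g)).sum(axis=0))
    return pd.Series(freqs, index=cohort.variant_ids)


def filter_variants_for_model(
    cohort: Cohort,
    bounds: tuple[float, float] = MAIN_FREQ_BOUNDS,
    missing_threshold: float = DEFAULT_MISSING_THRESHOLD,
) -> FilterResult:
    """Retain SNPs with alt-allele frequency strictly inside ``bounds``.

    Variants whose missingness exceeds ``missing_threshold`` are dropped
    first.  Raises if nothing survives.
    """
    lo, hi = bounds
    freqs = _alt_freqs(cohort)
    miss = pd.Series(np.isnan(cohort.genotypes).mean(axis=0), index=cohort.variant_ids)
    retained, rows = [], []
    for vid in cohort.variant_ids:
        if miss[vid] > missing_threshold:
            rows.append({"variant_id": vid, "reason": "missingness", "value": miss[vid]})
        elif not (lo < freqs[vid] < hi):
            rows.append({"variant_id": vid, "reason": "frequency", "value": freqs[vid]})
        else:
            retained.append(vid)
    if not retained:
        raise ValueError("no variants pass the modelling filters")
    exclusions = pd.DataFrame(rows, columns=["variant_id", "reason", "value"])
    for _, r in exclusions.iterrows():
        log.info("excluded %s from model (%s = %.4f)", r["variant_id"], r["reason"], r["value"])
    return FilterResult(retained, exclusions)


def enumerate_interactions(
    retained: list[str],
    cohort: Cohort,
    bounds: tuple[float, float] = PAIR_FREQ_BOUNDS,
) -> list[tuple[str, str]]:
    """All unordered within-gene pairs whose members' alt frequencies lie
    strictly inside ``bounds``, ordered by (gene, position)."""
    lo, hi = bounds
    freqs = _alt_freqs(cohort)
    by_gene: dict[str, list[tuple[int, str]]] = {}
    retained_set = set(retained)
    for v in cohort.variants:
        if v.variant_id in retained_set and lo < freqs[v.variant_id] < hi:
            by_gene.setdefault(v.gene, []).append((v.pos, v.variant_id))
    pairs: list[tuple[str, str]] = []
    for gene in sorted(by_gene):
        snps = [vid for _, vid in sorted(by_gene[gene])]
        for a in range(len(snps)):
            for b in range(a + 1, len(snps)):
                pairs.append((snps[a], snps[b]))
    return pairs


def _dummies(genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Het / hom-alt indicators with mean imputation of missing calls on the
    dummy scale (the imputation is logged by the caller)."""
    v1 = (genotypes == 1).astype(float)
    v2 = (genotypes == 2).astype(float)
    miss = np.isnan(genotypes)
    if miss.any():
        obs = ~miss
        v1[miss] = v1[obs].mean() if obs.any() else 0.0
        v2[miss] = v2[obs].mean() if obs.any() else 0.0
    return v1, v2


def build_design(
    cohort: Cohort,
    retained: list[str],
    pairs: list[tuple[str, str]],
    covariate_names: tuple[str, ...] = ("age", "sex", "weight", "height"),
    standardize_sex: bool = False,
) -> DesignMatrix:
    """Assemble the full design with its term registry.

    Constant (zero-variance) term columns are dropped with a warning; a
    group whose columns all vanish is dropped entirely.
    """
    if cohort.covariates is None:
        raise ValueError("cohort has no covariates")
    n = cohort.n_samples

    cov_cols, means, sds = [], [], []
    for name in covariate_names:
        if name == "sex":
            x = (cohort.covariates["sex"].to_numpy() == "male").astype(float)
            if standardize_sex:
                mu, sd = x.mean(), x.std(ddof=1)
                x = (x - mu) / sd
                means.append(mu); sds.append(sd)
                log.info("sex standardized (mean %.3f, sd %.3f)", mu, sd)
            else:
                means.append(0.0); sds.append(1.0)
        elif name == "bmi":
            raw = cohort.covariates["weight"].to_numpy(dtype=float) \
                / cohort.covariates["height"].to_numpy(dtype=float) ** 2
            mu, sd = raw.mean(), raw.std(ddof=1)
            x = (raw - mu) / sd
            means.append(mu); sds.append(sd)
        else:
            raw = cohort.covariates[name].to_numpy(dtype=float)
            mu, sd = raw.mean(), raw.std(ddof=1)
            if sd == 0:
                raise ValueError(f"covariate {name} is constant; cannot standardize")
            x = (raw - mu) / sd
            means.append(mu); sds.append(sd)
        cov_cols.append(x)
    X_cov = np.column_stack(cov_cols) if cov_cols else np.empty((n, 0))

    if np.isnan(cohort.genotypes).any():
        log.info("missing genotypes mean-imputed on the dummy scale")
    dummies = {vid: _dummies(cohort.genotype_column(vid)) for vid in retained}
    gene_of = {v.variant_id: v.gene for v in cohort.variants}

    columns: list[np.ndarray] = []
    terms: list[Term] = []
    groups: list[TermGroup] = []

    def add_group(kind, variants, gene, specs):
        gi = len(groups)
        kept_cols = []
        for vids, classes, col in specs:
            if col.std() == 0:
                log.warning("dropping constant design column %s %s", vids, classes)
                continue
            ci = len(columns)
            label = "x".join(f"{v}:{'het' if cl == 1 else 'hom'}" for v, cl in zip(vids, classes))
            columns.append(col)
            terms.append(Term(ci, "main" if kind == "snp" else "interaction",
                              vids, classes, gene, label, gi))
            kept_cols.append(ci)
        if kept_cols:
            groups.append(TermGroup(gi, kind, variants, gene, tuple(kept_cols)))
        else:
            log.warning("dropping empty term group %s", variants)

    for vid in retained:
        v1, v2 = dummies[vid]
        add_group("snp", (vid,), gene_of[vid],
                  [((vid,), (1,), v1), ((vid,), (2,), v2)])
    for vid1, vid2 in pairs:
        a1, a2 = dummies[vid1]
        b1, b2 = dummies[vid2]
        specs = [
            ((vid1, vid2), (1, 1), a1 * b1),
            ((vid1, vid2), (1, 2), a1 * b2),
            ((vid1, vid2), (2, 1), a2 * b1),
            ((vid1, vid2), (2, 2), a2 * b2),
        ]
        add_group("pair", (vid1, vid2), gene_of[vid1], specs)

    # re-number groups consecutively (some may have been dropped)
    remap: dict[int, int] = {}
    final_groups: list[TermGroup] = []
    for grp in groups:
        remap[grp.index] = len(final_groups)
        final_groups.append(TermGroup(len(final_groups), grp.kind, grp.variants,
                                      grp.gene, grp.columns))
    terms = [Term(t.column, t.kind, t.variants, t.classes, t.gene, t.label,
                  remap.get(t.group, -1)) for t in terms]

    X_terms = np.column_stack(columns) if columns else np.empty((n, 0))
    return DesignMatrix(
        samples=list(cohort.samples),
        covariate_names=list(covariate_names),
        X_cov=X_cov,
        cov_means=np.asarray(means),
        cov_sds=np.asarray(sds),
        X_terms=X_terms,
        terms=terms,
        groups=final_groups,
    )


def regenerate_column(cohort: Cohort, term: Term) -> np.ndarray:
    """Rebuild a registered term column from raw genotypes (registry
    round-trip check)."""
    cols = []
    for vid, cl in zip(term.variants, term.classes):
        v1, v2 = _dummies(cohort.genotype_column(vid))
        cols.append(v1 if cl == 1 else v2)
    out = cols[0]
    for c in cols[1:]:
        out = out * c
    return out


def default_design(cohort: Cohort, **kwargs) -> DesignMatrix:
    """Filter, enumerate interactions and build in one call."""
    filt = filter_variants_for_model(cohort)
    pairs = enumerate_interactions(filt.retained, cohort)
    return build_design(cohort, filt.retained, pairs, **kwargs)
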