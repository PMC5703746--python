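"""Shared in-memory data model for a genotyped, dosed cohort.

The central object is :class:`Cohort`: a samples x variants alt-allele-count
matrix, per-variant annotation (:class:`VariantRecord`), per-sample clinical
covariates (age in years, sex, weight in kg, height in m) and the weekly or
daily anticoagulant dose being modelled.  Genotypes are coded 0/1/2 as the
number of ALT alleles; missing calls are ``nan``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.nan

COVARIATE_COLUMNS = ("age", "sex", "weight", "height")


class Impact(str, enum.Enum):
    """SnpEff-style predicted functional impact class."""

    HIGH = "high"
    MODERATE = "moderate"
    MODIFIER = "modifier"
    LOW = "low"
    UNKNOWN = "unknown"


class DoseUnits(str, enum.Enum):
    MG_PER_WEEK = "mg_per_week"
    MG_PER_DAY = "mg_per_day"


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNV with its gene and impact annotation.

    ``variant_id`` is an rs identifier for known variants, or ``POS<pos>``
    for novel ones (no dbSNP entry); ``known`` is derived from that.
    """

    variant_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    gene: str = "unknown"
    impact: Impact = Impact.UNKNOWN

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.variant_id}: ref and alt alleles are identical")

    @property
    def known(self) -> bool:
        return self.variant_id.startswith("rs")

    @staticmethod
    def novel_id(pos: int) -> str:
        """Label for a variant without an rs identifier, e.g. ``POS42547668``."""
        return f"POS{pos}"


@dataclass
class Cohort:
    """Genotype matrix + annotations + clinical covariates + dose.

    genotypes: float array (n_samples, n_variants), entries in {0,1,2,nan}.
    covariates: DataFrame indexed by sample with columns age/sex/weight/height
    (sex coded as the strings ``male``/``female``).
    dose: positive per-sample Series aligned to ``samples``.
    """

    samples: list[str]
    genotypes: np.ndarray
    variants: list[VariantRecord]
    covariates: pd.DataFrame | None = None
    dose: pd.Series | None = None
    dose_units: DoseUnits = DoseUnits.MG_PER_WEEK

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        n, p = self.genotypes.shape
        if n != len(self.samples):
            raise ValueError(f"{len(self.samples)} samples but {n} genotype rows")
        if p != len(self.variants):
            raise ValueError(f"{len(self.variants)} variants but {p} genotype columns")
        if len(set(self.samples)) != n:
            raise ValueError("duplicated sample IDs")
        ids = [v.variant_id for v in self.variants]
        if len(set(ids)) != p:
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicated variant IDs: {dup}")
        ok = np.isnan(self.genotypes) | np.isin(self.genotypes, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("genotype entries must be 0, 1, 2 or missing")
        if self.covariates is not None:
            self.covariates = self.covariates.loc[self.samples]
        if self.dose is not None:
            self.dose = self.dose.loc[self.samples].astype(float)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def variant_index(self, variant_id: str) -> int:
        for i, v in enumerate(self.variants):
            if v.variant_id == variant_id:
                return i
        raise KeyError(variant_id)

    def genotype_column(self, variant_id: str) -> np.ndarray:
        return self.genotypes[:, self.variant_index(variant_id)]

    def convert_dose(self, units: DoseUnits) -> "Cohort":
        """Return a cohort with dose expressed in ``units`` (7 days/week)."""
        if self.dose is None or units == self.dose_units:
            return self
        factor = (1 / 7.0) if units == DoseUnits.MG_PER_DAY else 7.0
        out = Cohort(
            samples=list(self.samples),
            genotypes=self.genotypes.copy(),
            variants=list(self.variants),
            covariates=None if self.covariates is None else self.covariates.copy(),
            dose=self.dose * factor,
            dose_units=units,
        )
        return out


@dataclass
class ReferenceFrequencyTable:
    """Alt-allele frequencies of comparison populations (e.g. CHB/YRI/CEU).

    Stored as a tidy DataFrame with columns population, variant_id, alt_freq,
    n_chromosomes; used by the FST differentiation screen.
    """

    table: pd.DataFrame

    REQUIRED = ("population", "variant_id", "alt_freq", "n_chromosomes")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"reference table missing columns: {missing}")
        f = self.table["alt_freq"].to_numpy(dtype=float)
        if ((f < 0) | (f > 1)).any():
            raise ValueError("alt_freq outside [0, 1]")
        if (self.table["n_chromosomes"].to_numpy() < 2).any():
            raise ValueError("n_chromosomes must be >= 2")

    @property
    def populations(self) -> list[str]:
        return sorted(self.table["population"].unique())

    def for_population(self, population: str) -> pd.DataFrame:
        sub = self.table[self.table["population"] == population]
        return sub.set_index("variant_id")


@dataclass
class ValidationIssue:
    kind: str
    target: str
    detail: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)
    missingness: pd.Series | None = None

    @property
    def ok(self) -> bool:
        return not self.issues


def validate_cohort(cohort: Cohort) -> ValidationReport:
    """Report (never mutate) data problems relevant to dose modelling.

    Flags per-variant missingness, monomorphic variants and samples without a
    usable positive dose.
    """
    report = ValidationReport()
    g = cohort.genotypes
    miss = np.isnan(g).mean(axis=0)
    report.missingness = pd.Series(miss, index=cohort.variant_ids, name="missingness")
    for j, v in enumerate(cohort.variants):
        col = g[:, j]
        called = col[~np.isnan(col)]
        if called.size == 0:
            report.issues.append(ValidationIssue("all_missing", v.variant_id, "no called genotypes"))
        elif np.all(called == called[0]):
            report.issues.append(
                ValidationIssue("monomorphic", v.variant_id, f"all calls equal {int(called[0])}")
            )
    if cohort.dose is not None:
        for s, d in cohort.dose.items():
            if not np.isfinite(d):
                report.issues.append(ValidationIssue("missing_dose", str(s), "dose missing"))
            elif d <= 0:
                report.issues.append(ValidationIssue("nonpositive_dose", str(s), f"dose = {d}"))
    else:
        report.issues.append(ValidationIssue("missing_dose", "<cohort>", "no dose column"))
    return report
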