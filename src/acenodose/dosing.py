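"""Deterministic dose calculator.

Evaluates the two published acenocoumarol dosing equations — Model 1
(with the VKORC1 diplotype interaction) and Model 2 (single-SNP VKORC1
terms) — and any fitted model exported from the selection module.

Ln Dose (Model 1) = -0.6935 - 0.0071*age + 0.0035*weight - 0.1136 (if male)
  + 1.0709*height - 0.213 (VKORC1 rs8050894 C/G and rs9934438 G/A)
  - 0.719 (G/G and A/A) + 0.899 (CYP2D8P POS42547668 T/C)
  + 0.203 (SULT1A1 rs11648192 C/T)

Ln Dose (Model 2) = -0.5846 - 0.0069*age + 0.0045*weight - 0.0945 (if male)
  + 0.9795*height - 0.239 (rs9934438 G/A) - 0.529 (A/A)
  + 1.092 (POS42547668 T/C) + 0.188 (rs11648192 C/T)

The exponential of the ln-dose is labelled "model units": the source
cohort reports weekly doses in its demographics but daily doses in its
worked predictions, and the equations themselves do not disambiguate; a
config override attaches a concrete unit.  Heterozygote clauses such as
"C/G" are unordered; homozygous reference is the implicit baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort

log = logging.getLogger("acenodose")

VKORC1_RS8050894 = "rs8050894"
VKORC1_RS9934438 = "rs9934438"
CYP2D8P_POS42547668 = "POS42547668"
SULT1A1_RS11648192 = "rs11648192"

# alt-allele orientation of the modelled loci, used to translate allele
# strings like "C/G" into alt-allele counts
_LOCUS_ALLELES = {
    VKORC1_RS8050894: ("C", "G"),
    VKORC1_RS9934438: ("G", "A"),
    CYP2D8P_POS42547668: ("T", "C"),
    SULT1A1_RS11648192: ("C", "T"),
}


@dataclass(frozen=True)
class GenotypeClause:
    """An additive ln-dose effect triggered by joint genotype conditions.

    ``conditions`` is a tuple of (variant_id, genotype_class) with class 1 =
    heterozygous, 2 = homozygous alt; all must hold for the effect to apply.
    """

    conditions: tuple[tuple[str, int], ...]
    effect: float
    description: str = ""


@dataclass(frozen=True)
class DoseModelCoefficients:
    label: str
    intercept: float
    age: float                 # per year
    weight: float              # per kg
    male: float                # indicator
    height: float              # per metre
    clauses: tuple[GenotypeClause, ...]
    provenance: str = ""
    units: str = "model units"

    @property
    def loci(self) -> list[str]:
        seen: dict[str, None] = {}
        for cl in self.clauses:
            for vid, _ in cl.conditions:
                seen.setdefault(vid)
        return list(seen)


MODEL1 = DoseModelCoefficients(
    label="model1_interactions",
    intercept=-0.6935,
    age=-0.0071,
    weight=0.0035,
    male=-0.1136,
    height=1.0709,
    clauses=(
        GenotypeClause(((VKORC1_RS8050894, 1), (VKORC1_RS9934438, 1)), -0.213,
                       "VKORC1 rs8050894 C/G and rs9934438 G/A"),
        GenotypeClause(((VKORC1_RS8050894, 2), (VKORC1_RS9934438, 2)), -0.719,
                       "VKORC1 rs8050894 G/G and rs9934438 A/A"),
        GenotypeClause(((CYP2D8P_POS42547668, 1),), 0.899,
                       "CYP2D8P POS42547668 T/C"),
        GenotypeClause(((SULT1A1_RS11648192, 1),), 0.203,
                       "SULT1A1 rs11648192 C/T"),
    ),
    provenance="published interaction dosing equation",
)

MODEL2 = DoseModelCoefficients(
    label="model2_no_interactions",
    intercept=-0.5846,
    age=-0.0069,
    weight=0.0045,
    male=-0.0945,
    height=0.9795,
    clauses=(
        GenotypeClause(((VKORC1_RS9934438, 1),), -0.239, "VKORC1 rs9934438 G/A"),
        GenotypeClause(((VKORC1_RS9934438, 2),), -0.529, "VKORC1 rs9934438 A/A"),
        GenotypeClause(((CYP2D8P_POS42547668, 1),), 1.092, "CYP2D8P POS42547668 T/C"),
        GenotypeClause(((SULT1A1_RS11648192, 1),), 0.188, "SULT1A1 rs11648192 C/T"),
    ),
    provenance="published no-interaction dosing equation",
)

_PUBLISHED = {MODEL1.label: MODEL1, MODEL2.label: MODEL2,
              "model1": MODEL1, "model2": MODEL2}


def published_model(label: str) -> DoseModelCoefficients:
    """The exact printed coefficients of one published dosing equation."""
    try:
        return _PUBLISHED[label]
    except KeyError:
        raise ValueError(
            f"unknown model label {label!r}; choose from {sorted(_PUBLISHED)}"
        ) from None


def genotype_class_from_alleles(variant_id: str, call: str) -> int:
    """Translate an unordered allele-string call (e.g. "C/G") to 0/1/2."""
    ref, alt = _LOCUS_ALLELES[variant_id]
    alleles = call.replace("|", "/").upper().split("/")
    if len(alleles) != 2 or any(a not in (ref, alt) for a in alleles):
        raise ValueError(f"{variant_id}: cannot interpret genotype call {call!r}")
    return sum(a == alt for a in alleles)


@dataclass(frozen=True)
class PatientRecord:
    age: float
    sex: str                   # "male" | "female"
    weight: float
    height: float
    genotypes: dict = field(default_factory=dict)   # variant_id -> 0/1/2 or "C/G"

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be male/female, got {self.sex!r}")
        for name, v in (("age", self.age), ("weight", self.weight), ("height", self.height)):
            if v < 0:
                raise ValueError(f"{name} must be non-negative")

    def genotype_class(self, variant_id: str) -> int | None:
        call = self.genotypes.get(variant_id)
        if call is None:
            return None
        if isinstance(call, str):
            return genotype_class_from_alleles(variant_id, call)
        g = int(call)
        if g not in (0, 1, 2):
            raise ValueError(f"{variant_id}: genotype must be 0/1/2, got {call!r}")
        return g


def ln_dose(
    model: DoseModelCoefficients,
    patient: PatientRecord,
    assume_reference: bool = False,
) -> float:
    """Exact ln-dose: intercept + covariate products + matched clauses.

    Missing genotype calls are a hard error unless ``assume_reference``
    (then treated as homozygous reference and logged).
    """
    calls: dict[str, int] = {}
    for vid in model.loci:
        g = patient.genotype_class(vid)
        if g is None:
            if not assume_reference:
                raise ValueError(f"patient lacks a genotype call at {vid}")
            log.info("assuming homozygous reference at %s", vid)
            g = 0
        calls[vid] = g
    value = (model.intercept
             + model.age * patient.age
             + model.weight * patient.weight
             + (model.male if patient.sex == "male" else 0.0)
             + model.height * patient.height)
    matched_per_variant: dict[str, int] = {}
    for clause in model.clauses:
        if all(calls[vid] == cls for vid, cls in clause.conditions):
            for vid, _ in clause.conditions:
                if matched_per_variant.get(vid, 0):
                    raise RuntimeError(
                        f"contradictory clauses matched at {vid} in {model.label}"
                    )
                matched_per_variant[vid] = 1
            value += clause.effect
    return value


def predict_dose(
    model: DoseModelCoefficients,
    patient: PatientRecord,
    assume_reference: bool = False,
) -> float:
    """exp(ln_dose); the unit label comes from the model (default
    "model units")."""
    return float(np.exp(ln_dose(model, patient, assume_reference)))


def batch_predict(
    model: DoseModelCoefficients,
    cohort: Cohort,
    assume_reference: bool = False,
) -> pd.DataFrame:
    """Per-sample predictions for a cohort carrying the model's loci.

    Samples with missing calls at a modelled locus are skipped with a log
    line (unless ``assume_reference``).
    """
    cov = cohort.covariates
    if cov is None:
        raise ValueError("cohort has no covariates")
    loci = model.loci
    idx = {}
    for vid in loci:
        try:
            idx[vid] = cohort.variant_index(vid)
        except KeyError:
            if not assume_reference:
                raise ValueError(f"cohort does not carry modelled locus {vid}") from None
    rows = []
    for k, s in enumerate(cohort.samples):
        genos = {}
        skip = False
        for vid in loci:
            if vid not in idx:
                genos[vid] = 0
                continue
            g = cohort.genotypes[k, idx[vid]]
            if np.isnan(g):
                if assume_reference:
                    genos[vid] = 0
                else:
                    log.info("skipping %s: missing call at %s", s, vid)
                    skip = True
                    break
            else:
                genos[vid] = int(g)
        if skip:
            continue
        patient = PatientRecord(
            age=float(cov.loc[s, "age"]), sex=str(cov.loc[s, "sex"]),
            weight=float(cov.loc[s, "weight"]), height=float(cov.loc[s, "height"]),
            genotypes=genos,
        )
        ln = ln_dose(model, patient, assume_reference)
        observed = float(cohort.dose.loc[s]) if cohort.dose is not None else np.nan
        rows.append({"sample": s, "ln_dose": ln, "dose": float(np.exp(ln)),
                     "observed_dose": observed,
                     "residual": float(np.exp(ln)) - observed})
    return pd.DataFrame(rows, columns=["sample", "ln_dose", "dose",
                                       "observed_dose", "residual"]).set_index("sample")


def evaluate_selected_on_cohort(selected, cohort: Cohort) -> pd.Series:
    """Ln-dose of a fitted :class:`~acenodose.selection.SelectedModel` on a
    cohort, rebuilt from raw genotypes through the term registry and the
    stored standardization constants.

    On the cohort the model was fitted to this equals the posterior-mean
    linear predictor to machine precision.
    """
    from .design import regenerate_column

    design = selected.design
    cov = cohort.covariates
    n = cohort.n_samples
    eta = np.full(n, selected.intercept)
    for j, name in enumerate(design.covariate_names):
        if name == "sex":
            x = (cov["sex"].to_numpy() == "male").astype(float)
        elif name == "bmi":
            x = cov["weight"].to_numpy(dtype=float) / cov["height"].to_numpy(dtype=float) ** 2
        else:
            x = cov[name].to_numpy(dtype=float)
        eta += selected.alpha[j] * (x - design.cov_means[j]) / design.cov_sds[j]
    for t in design.terms:
        b = selected.beta[t.column]
        if b != 0.0:
            eta += b * regenerate_column(cohort, t)
    return pd.Series(eta, index=cohort.samples, name="ln_dose")
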