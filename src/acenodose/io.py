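"""Reading and writing the external formats: VCF genotypes, covariate and
reference-frequency tables, and YAML configuration."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from .cohort import (
    Cohort,
    DoseUnits,
    Impact,
    ReferenceFrequencyTable,
    VariantRecord,
)

log = logging.getLogger("acenodose")

GENE_INFO_KEY = "GENE"
IMPACT_INFO_KEY = "IMPACT"


class VcfParseError(ValueError):
    pass


class SchemaError(ValueError):
    pass


def read_vcf(
    path: str | Path,
    gene_key: str = GENE_INFO_KEY,
    impact_key: str = IMPACT_INFO_KEY,
) -> tuple[np.ndarray, list[VariantRecord], list[str]]:
    """Read a VCF into (genotype matrix, variant records, sample IDs).

    Genotypes are alt-allele counts relative to the ALT field (0/1/2);
    missing GT becomes nan.  Gene and impact annotations are taken from the
    named INFO keys when present, otherwise "unknown".  Multiallelic records
    are rejected.
    """
    path = str(path)
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vf.header.samples)
    records: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    seen: set[str] = set()
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            raise VcfParseError(
                f"{path}: record at {rec.chrom}:{rec.pos} is not biallelic"
            )
        vid = rec.id if rec.id else VariantRecord.novel_id(rec.pos)
        if vid in seen:
            raise VcfParseError(f"{path}: duplicate variant ID {vid}")
        seen.add(vid)
        gene = rec.info.get(gene_key, "unknown")
        impact_raw = str(rec.info.get(impact_key, "unknown")).lower()
        try:
            impact = Impact(impact_raw)
        except ValueError:
            impact = Impact.UNKNOWN
        records.append(
            VariantRecord(
                variant_id=vid,
                chrom=rec.chrom,
                pos=rec.pos,
                ref_allele=rec.ref,
                alt_allele=rec.alts[0],
                gene=str(gene),
                impact=impact,
            )
        )
        row = np.empty(len(samples))
        for k, s in enumerate(samples):
            alleles = rec.samples[s]["GT"]
            if alleles is None or any(a is None for a in alleles):
                row[k] = np.nan
            else:
                row[k] = float(sum(alleles))
        rows.append(row)
    vf.close()
    if not rows:
        genotypes = np.empty((len(samples), 0))
    else:
        genotypes = np.column_stack(rows)
    return genotypes, records, samples


def write_vcf(
    path: str | Path,
    genotypes: np.ndarray,
    variants: list[VariantRecord],
    samples: list[str],
    gene_key: str = GENE_INFO_KEY,
    impact_key: str = IMPACT_INFO_KEY,
) -> None:
    """Write an uncompressed VCF 4.2 that :func:`read_vcf` round-trips."""
    header = pysam.VariantHeader()
    header.add_meta("INFO", items=[("ID", gene_key), ("Number", "1"),
                                   ("Type", "String"), ("Description", "Gene symbol")])
    header.add_meta("INFO", items=[("ID", impact_key), ("Number", "1"),
                                   ("Type", "String"), ("Description", "Predicted impact")])
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"),
                                     ("Type", "String"), ("Description", "Genotype")])
    for chrom in dict.fromkeys(v.chrom for v in variants):
        header.contigs.add(chrom)
    for s in samples:
        header.add_sample(s)
    out = pysam.VariantFile(str(path), "w", header=header)
    for j, v in enumerate(variants):
        rec = out.new_record(
            contig=v.chrom,
            start=v.pos - 1,
            stop=v.pos - 1 + len(v.ref_allele),
            alleles=(v.ref_allele, v.alt_allele),
            id=v.variant_id if v.known else None,
        )
        rec.info[gene_key] = v.gene
        rec.info[impact_key] = v.impact.value
        for k, s in enumerate(samples):
            g = genotypes[k, j]
            if np.isnan(g):
                rec.samples[s]["GT"] = (None, None)
            elif g == 0:
                rec.samples[s]["GT"] = (0, 0)
            elif g == 1:
                rec.samples[s]["GT"] = (0, 1)
            else:
                rec.samples[s]["GT"] = (1, 1)
        out.write(rec)
    out.close()


REQUIRED_COVARIATE_COLUMNS = ("sample", "age", "sex", "weight", "height", "dose")


def read_covariates(
    path: str | Path,
    dose_units: DoseUnits = DoseUnits.MG_PER_WEEK,
    file_units: DoseUnits = DoseUnits.MG_PER_WEEK,
    sep: str | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Read the clinical table (age y, sex, weight kg, height m, dose).

    Returns (covariates indexed by sample, dose Series converted from
    ``file_units`` to ``dose_units``).
    """
    import csv

    try:
        df = pd.read_csv(path, sep=sep, engine="python")
    except (pd.errors.EmptyDataError, csv.Error) as exc:
        raise SchemaError(f"{path}: empty or undelimited covariate file") from exc
    missing = [c for c in REQUIRED_COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    df = df.copy()
    df["sample"] = df["sample"].astype(str)
    df = df.set_index("sample")
    sex = df["sex"].astype(str).str.lower().str.strip()
    sex = sex.replace({"m": "male", "f": "female"})
    bad_sex = sorted(set(sex) - {"male", "female"})
    if bad_sex:
        raise SchemaError(f"{path}: unrecognized sex values {bad_sex}")
    cov = pd.DataFrame(
        {
            "age": df["age"].astype(float),
            "sex": sex,
            "weight": df["weight"].astype(float),
            "height": df["height"].astype(float),
        }
    )
    dose = df["dose"].astype(float)
    nonpos = dose.index[~(dose > 0)].tolist()
    if nonpos:
        raise ValueError(f"{path}: non-positive dose for samples {nonpos}")
    if file_units != dose_units:
        dose = dose / 7.0 if dose_units == DoseUnits.MG_PER_DAY else dose * 7.0
    return cov, dose.rename("dose")


def write_covariates(path: str | Path, covariates: pd.DataFrame, dose: pd.Series) -> None:
    out = covariates.copy()
    out["dose"] = dose
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


def read_cohort(
    vcf_path: str | Path,
    covariates_path: str | Path,
    dose_units: DoseUnits = DoseUnits.MG_PER_WEEK,
    file_units: DoseUnits = DoseUnits.MG_PER_WEEK,
) -> Cohort:
    genotypes, variants, samples = read_vcf(vcf_path)
    cov, dose = read_covariates(covariates_path, dose_units=dose_units, file_units=file_units)
    missing = [s for s in samples if s not in cov.index]
    if missing:
        raise SchemaError(f"samples in VCF but not covariate table: {missing}")
    return Cohort(
        samples=samples,
        genotypes=genotypes,
        variants=variants,
        covariates=cov,
        dose=dose,
        dose_units=dose_units,
    )


def read_reference_frequencies(path: str | Path, sep: str | None = None) -> ReferenceFrequencyTable:
    df = pd.read_csv(path, sep=sep, engine="python")
    return ReferenceFrequencyTable(df)


def write_reference_frequencies(path: str | Path, ref: ReferenceFrequencyTable) -> None:
    ref.table.to_csv(path, sep="\t", index=False)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a YAML mapping")
    return cfg


def setup_logging(run_log: str | Path | None = None, level: int = logging.INFO) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if run_log is not None:
        handlers.append(logging.FileHandler(str(run_log)))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
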