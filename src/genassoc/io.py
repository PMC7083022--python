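"""Cohort input/output: genotype tables, phenotype tables, optional VCF.

Genotype tables are delimited text with a ``subject_id`` column plus one
column per marker holding ``"X/Y"`` genotype strings in the marker's own
alleles (order-insensitive); the missing token defaults to ``"NA"``.
Phenotype tables carry case/control status, covariates and — for cases
only — clinicopathological fields; a control with a non-missing
clinicopathological value is rejected at read time, because the subgroup
analyses are case-only by design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .markers import MISSING, MarkerDef
from .models import GenotypeCounts

__all__ = [
    "CASE_ONLY_FIELDS",
    "SubjectRecord",
    "CohortTable",
    "read_genotype_table",
    "read_phenotype_table",
    "read_genotype_vcf",
]

#: Clinicopathological fields defined for cases only.
CASE_ONLY_FIELDS = (
    "er",
    "pgr",
    "her2",
    "ki67",
    "lymph_node",
    "family_history",
    "age_at_diagnosis",
    "menopause_at_diagnosis",
)


def _is_missing(v, missing_token: str) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    return isinstance(v, str) and v.strip() in ("", missing_token)


@dataclass
class SubjectRecord:
    """One subject: status, covariates, and (cases only) clinical fields."""

    subject_id: str
    status: bool  # True = case
    covariates: Dict[str, object] = field(default_factory=dict)
    clinical: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if not self.status:
            bad = [k for k, v in self.clinical.items() if v is not MISSING]
            if bad:
                raise ValueError(
                    f"control {self.subject_id!r} has clinicopathological values "
                    f"for {bad}; these fields are case-only"
                )


def _read_delimited(path, sep: Optional[str]) -> pd.DataFrame:
    # sep=None lets pandas sniff the delimiter (csv.Sniffer via python engine)
    return pd.read_csv(path, sep=sep, engine="python" if sep is None else "c",
                       dtype=str, keep_default_na=False)


def read_genotype_table(
    path,
    marker_defs: Mapping[str, MarkerDef],
    sep: Optional[str] = None,
    missing_token: str = "NA",
) -> pd.DataFrame:
    """Read a genotype table into a subjects x markers dosage frame.

    Every non-``subject_id`` column must be a known marker; cells are
    ``"X/Y"`` strings in the marker's alleles.  Dosage counts the alt
    allele.  Unknown allele characters are an error, not MISSING.
    Returns a DataFrame indexed by subject_id with nullable-integer dosage
    columns.
    """
    raw = _read_delimited(path, sep)
    if "subject_id" not in raw.columns:
        raise ValueError(f"{path}: genotype table must have a 'subject_id' column")
    unknown = [c for c in raw.columns if c != "subject_id" and c not in marker_defs]
    if unknown:
        raise ValueError(f"{path}: unknown marker column(s): {unknown}")
    dup = raw["subject_id"][raw["subject_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate subject_id(s): {sorted(set(dup))}")

    out = {}
    for col in raw.columns:
        if col == "subject_id":
            continue
        marker = marker_defs[col]
        dosages = []
        for row_idx, cell in zip(raw.index, raw[col]):
            if _is_missing(cell, missing_token):
                dosages.append(pd.NA)
                continue
            try:
                dosages.append(marker.dosage_from_cell(cell))
            except ValueError as e:
                raise ValueError(f"{path}: row {row_idx + 2}, column {col!r}: {e}") from e
        out[col] = dosages
    geno = pd.DataFrame(out, index=pd.Index(raw["subject_id"], name="subject_id"),
                        dtype="Int64")
    return geno


def read_phenotype_table(
    path,
    sep: Optional[str] = None,
    case_label: str = "case",
    control_label: str = "control",
    missing_token: str = "NA",
) -> List[SubjectRecord]:
    """Read a phenotype table into typed subject records.

    The ``status`` column must hold the configured case/control labels.
    Columns in :data:`CASE_ONLY_FIELDS` become clinical fields; anything
    else becomes a covariate (numeric where possible).  Controls with
    non-missing clinical values are rejected.
    """
    raw = _read_delimited(path, sep)
    for col in ("subject_id", "status"):
        if col not in raw.columns:
            raise ValueError(f"{path}: phenotype table must have a {col!r} column")
    dup = raw["subject_id"][raw["subject_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate subject_id(s): {sorted(set(dup))}")

    records = []
    for row_idx, row in raw.iterrows():
        label = row["status"].strip()
        if label == case_label:
            status = True
        elif label == control_label:
            status = False
        else:
            raise ValueError(
                f"{path}: row {row_idx + 2}: unknown status label {label!r} "
                f"(expected {case_label!r} or {control_label!r})"
            )
        covariates, clinical = {}, {}
        for col in raw.columns:
            if col in ("subject_id", "status"):
                continue
            v = row[col]
            if _is_missing(v, missing_token):
                value = MISSING
            else:
                try:
                    value = float(v)
                    if value == int(value):
                        value = int(value)
                except ValueError:
                    value = v.strip()
            if col in CASE_ONLY_FIELDS:
                clinical[col] = value
            else:
                covariates[col] = value
        records.append(
            SubjectRecord(str(row["subject_id"]), status, covariates, clinical)
        )
    return records


@dataclass
class CohortTable:
    """Subjects x markers genotype matrix joined to phenotypes.

    ``phenotypes`` is indexed by subject_id with a boolean ``status``
    column (True = case) plus covariate/clinical columns; ``genotypes`` is
    indexed by subject_id with one nullable-integer dosage column per
    marker.  The two indexes must agree.
    """

    phenotypes: pd.DataFrame
    genotypes: pd.DataFrame
    markers: Dict[str, MarkerDef]

    def __post_init__(self):
        if not self.phenotypes.index.equals(self.genotypes.index):
            missing = set(self.phenotypes.index) ^ set(self.genotypes.index)
            raise ValueError(
                f"phenotype and genotype tables cover different subjects: {sorted(missing)[:5]}..."
                if missing else "phenotype/genotype subject order differs"
            )
        unknown = [c for c in self.genotypes.columns if c not in self.markers]
        if unknown:
            raise ValueError(f"genotype columns without a MarkerDef: {unknown}")

    # -- constructors -------------------------------------------------------------

    @classmethod
    def from_records(cls, records: Sequence[SubjectRecord],
                     genotypes: pd.DataFrame,
                     markers: Mapping[str, MarkerDef]) -> "CohortTable":
        rows = []
        for r in records:
            row = {"status": r.status}
            row.update(r.covariates)
            row.update(r.clinical)
            rows.append(row)
        pheno = pd.DataFrame(rows, index=pd.Index([r.subject_id for r in records],
                                                  name="subject_id"))
        geno = genotypes.reindex(pheno.index)
        return cls(pheno, geno, dict(markers))

    @classmethod
    def from_files(cls, genotype_path, phenotype_path,
                   markers: Mapping[str, MarkerDef], **kw) -> "CohortTable":
        records = read_phenotype_table(phenotype_path, **{
            k: v for k, v in kw.items()
            if k in ("sep", "case_label", "control_label", "missing_token")})
        geno = read_genotype_table(genotype_path, markers, **{
            k: v for k, v in kw.items() if k in ("sep", "missing_token")})
        pheno_ids = [r.subject_id for r in records]
        if set(pheno_ids) != set(geno.index):
            raise ValueError("genotype and phenotype tables cover different subjects")
        return cls.from_records(records, geno, markers)

    # -- accessors ----------------------------------------------------------------

    @property
    def n_cases(self) -> int:
        return int(self.phenotypes["status"].sum())

    @property
    def n_controls(self) -> int:
        return int((~self.phenotypes["status"]).sum())

    def subset(self, mask) -> "CohortTable":
        return CohortTable(self.phenotypes[mask], self.genotypes[mask], self.markers)

    def cases(self) -> "CohortTable":
        return self.subset(self.phenotypes["status"].astype(bool).values)

    def genotype_counts(self, marker_id: str, mask=None) -> GenotypeCounts:
        col = self.genotypes[marker_id]
        if mask is not None:
            col = col[mask]
        return GenotypeCounts.from_dosages(
            [None if pd.isna(v) else int(v) for v in col]
        )

    def group_counts(self, marker_id: str):
        """(cases, controls) GenotypeCounts for one marker, complete cases."""
        status = self.phenotypes["status"].astype(bool).values
        return (
            self.genotype_counts(marker_id, mask=status),
            self.genotype_counts(marker_id, mask=~status),
        )

    # -- output -------------------------------------------------------------------

    def write(self, genotype_path, phenotype_path, sep: str = "\t",
              missing_token: str = "NA",
              case_label: str = "case", control_label: str = "control") -> None:
        """Write genotype and phenotype tables in the dialect the readers consume."""
        geno_out = pd.DataFrame(index=self.genotypes.index)
        for m_id in self.genotypes.columns:
            marker = self.markers[m_id]
            geno_out[m_id] = [
                missing_token if pd.isna(v) else marker.cell_from_dosage(int(v))
                for v in self.genotypes[m_id]
            ]
        geno_out.reset_index().to_csv(genotype_path, sep=sep, index=False)

        pheno_out = self.phenotypes.copy()
        pheno_out["status"] = np.where(pheno_out["status"].astype(bool),
                                       case_label, control_label)
        pheno_out = pheno_out.fillna(missing_token)
        pheno_out.reset_index().to_csv(phenotype_path, sep=sep, index=False)


def read_genotype_vcf(path, marker_defs: Mapping[str, MarkerDef]) -> pd.DataFrame:
    """Read dosages for the configured markers from a VCF (matching by ID).

    GT fields are mapped to alt-allele dosage against the MarkerDef
    alleles; multi-allelic records and REF/ALT disagreeing with the marker
    definition are rejected.  Coordinates are ignored.  Requires cyvcf2.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    data = {}
    for variant in vcf:
        if variant.ID not in marker_defs:
            continue
        marker = marker_defs[variant.ID]
        if len(variant.ALT) != 1:
            raise ValueError(f"{variant.ID}: multi-allelic records are not supported")
        if variant.REF != marker.ref_allele or variant.ALT[0] != marker.alt_allele:
            raise ValueError(
                f"{variant.ID}: VCF alleles {variant.REF}/{variant.ALT[0]} do not match "
                f"marker definition {marker.ref_allele}/{marker.alt_allele}"
            )
        dosages = []
        for gt in variant.genotypes:  # [allele1, allele2, phased]
            alleles = gt[:-1]
            if any(al < 0 for al in alleles):
                dosages.append(pd.NA)
            else:
                dosages.append(int(sum(alleles)))
        data[variant.ID] = dosages
    return pd.DataFrame(data, index=pd.Index(samples, name="subject_id"), dtype="Int64")
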