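"""Subject-level cohort data model and aggregation to contingency tables.

The cohort is the unit every analysis consumes: one binary phenotype
(1 = case, 0 = control), per-variant genotype calls stored as copies of
the declared alternate allele (0/1/2, -1 = missing), and binary lifestyle
covariates plus age in years.  Aggregation collapses the cohort into the
2x3 genotype count tables and 2x2 contrasts that the association,
permutation and interaction statistics operate on.

Genotype orientation is explicit: every :class:`VariantDef` declares which
homozygote is the baseline for odds-ratio contrasts.  The baseline is never
inferred from allele frequency — for promoter variants the study baseline
may well be the *minor* homozygote.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

MISSING = -1  # sentinel for a missing genotype call

__all__ = [
    "MISSING",
    "VariantDef",
    "Subject",
    "CohortTable",
    "GenotypeCountTable",
    "TwoByTwo",
    "CohortSchema",
    "read_cohort",
    "write_cohort",
    "genotype_counts",
    "collapse",
    "crosstab_covariate",
]


@dataclass(frozen=True)
class VariantDef:
    """A biallelic variant with an explicit odds-ratio baseline genotype.

    Parameters
    ----------
    id:
        Variant identifier, e.g. ``"rs73013281"``.
    allele_ref, allele_alt:
        Single-character reference and alternate alleles.  Calls are stored
        as copies of ``allele_alt``.
    reference_genotype:
        ``"ref_hom"`` (0 copies of alt) or ``"alt_hom"`` (2 copies); the
        homozygote used as the baseline of every genetic contrast.
    """

    id: str
    allele_ref: str
    allele_alt: str
    reference_genotype: str = "ref_hom"

    def __post_init__(self) -> None:
        if len(self.allele_ref) != 1 or len(self.allele_alt) != 1:
            raise ValueError(f"{self.id}: alleles must be single characters")
        if self.allele_ref == self.allele_alt:
            raise ValueError(f"{self.id}: ref and alt alleles must differ")
        if self.reference_genotype not in ("ref_hom", "alt_hom"):
            raise ValueError(
                f"{self.id}: reference_genotype must be 'ref_hom' or 'alt_hom', "
                f"got {self.reference_genotype!r}"
            )

    @property
    def reference_call(self) -> int:
        """Alt-allele copy count of the baseline homozygote (0 or 2)."""
        return 0 if self.reference_genotype == "ref_hom" else 2

    def genotype_label(self, call: int) -> str:
        """Two-letter genotype string for an alt-copy count, e.g. 1 -> 'CT'."""
        if call == 0:
            return self.allele_ref * 2
        if call == 1:
            return self.allele_ref + self.allele_alt
        if call == 2:
            return self.allele_alt * 2
        raise ValueError(f"invalid call {call}")

    def parse_call(self, token: object, missing_token: str = "NA") -> int:
        """Parse a genotype token into an alt-copy count.

        Accepts two-character allele strings in either order ("CT" == "TC"),
        integer copy counts 0/1/2, and the declared missing token.  Any
        other token is treated as missing.
        """
        if token is None:
            return MISSING
        if isinstance(token, float):
            if np.isnan(token):
                return MISSING
            token = int(token)
        if isinstance(token, (int, np.integer)):
            return int(token) if token in (0, 1, 2) else MISSING
        s = str(token).strip()
        if s == missing_token or s == "":
            return MISSING
        if s in ("0", "1", "2"):
            return int(s)
        if len(s) == 2:
            alleles = {self.allele_ref, self.allele_alt}
            if set(s) <= alleles:
                return sum(1 for ch in s if ch == self.allele_alt)
        return MISSING


@dataclass
class Subject:
    """One study participant (a row view into :class:`CohortTable`)."""

    id: str
    phenotype: int
    genotypes: dict[str, int]
    covariates: dict[str, float]
    age: float | None = None


class CohortTable:
    """Array-backed case-control cohort.

    Internally the cohort stores one int8 phenotype vector, one int8 call
    vector per variant (-1 missing) and one float vector per covariate
    (NaN missing); :class:`Subject` objects are materialised on demand.
    """

    def __init__(
        self,
        phenotype: Sequence[int] | np.ndarray,
        variants: Sequence[VariantDef],
        genotypes: Mapping[str, Sequence[int] | np.ndarray],
        covariates: Mapping[str, Sequence[float] | np.ndarray] | None = None,
        age: Sequence[float] | np.ndarray | None = None,
        subject_ids: Sequence[str] | None = None,
    ) -> None:
        self.phenotype = np.asarray(phenotype, dtype=np.int8)
        if not np.isin(self.phenotype, (0, 1)).all():
            raise ValueError("phenotype values must be 0 (control) or 1 (case)")
        n = self.phenotype.size
        self.variants: dict[str, VariantDef] = {v.id: v for v in variants}
        if len(self.variants) != len(variants):
            raise ValueError("duplicate variant ids")
        self._genotypes: dict[str, np.ndarray] = {}
        for vid, calls in genotypes.items():
            if vid not in self.variants:
                raise ValueError(f"genotypes given for undeclared variant {vid!r}")
            arr = np.asarray(calls, dtype=np.int8)
            if arr.size != n:
                raise ValueError(f"genotype vector for {vid!r} has wrong length")
            if not np.isin(arr, (MISSING, 0, 1, 2)).all():
                raise ValueError(f"genotype calls for {vid!r} outside {{-1,0,1,2}}")
            self._genotypes[vid] = arr
        self._covariates: dict[str, np.ndarray] = {}
        for name, vals in (covariates or {}).items():
            arr = np.asarray(vals, dtype=float)
            if arr.size != n:
                raise ValueError(f"covariate {name!r} has wrong length")
            ok = np.isnan(arr) | np.isin(arr, (0.0, 1.0))
            if not ok.all():
                raise ValueError(f"covariate {name!r} must be binary 0/1 (NaN = missing)")
            self._covariates[name] = arr
        self.age = None if age is None else np.asarray(age, dtype=float)
        if self.age is not None and self.age.size != n:
            raise ValueError("age vector has wrong length")
        if subject_ids is None:
            subject_ids = [f"S{i + 1}" for i in range(n)]
        self.subject_ids = list(map(str, subject_ids))
        if len(set(self.subject_ids)) != n:
            raise ValueError("subject ids must be unique")

    # -- basic introspection ------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return self.phenotype.size

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    @property
    def n_controls(self) -> int:
        return self.n_subjects - self.n_cases

    @property
    def covariate_names(self) -> list[str]:
        return list(self._covariates)

    def calls(self, variant_id: str) -> np.ndarray:
        """Alt-copy call vector (-1 missing) for one variant."""
        if variant_id not in self._genotypes:
            raise KeyError(f"unknown variant {variant_id!r}")
        return self._genotypes[variant_id]

    def covariate(self, name: str) -> np.ndarray:
        if name not in self._covariates:
            raise KeyError(f"unknown covariate {name!r}")
        return self._covariates[name]

    def variant(self, variant_id: str) -> VariantDef:
        if variant_id not in self.variants:
            raise KeyError(f"unknown variant {variant_id!r}")
        return self.variants[variant_id]

    def subjects(self) -> Iterable[Subject]:
        for i in range(self.n_subjects):
            yield Subject(
                id=self.subject_ids[i],
                phenotype=int(self.phenotype[i]),
                genotypes={v: int(g[i]) for v, g in self._genotypes.items()},
                covariates={
                    k: float(v[i]) for k, v in self._covariates.items()
                    if not np.isnan(v[i])
                },
                age=None if self.age is None or np.isnan(self.age[i]) else float(self.age[i]),
            )

    def subset(self, mask: np.ndarray) -> "CohortTable":
        """Row-subset cohort (used by stratified analyses)."""
        mask = np.asarray(mask, dtype=bool)
        return CohortTable(
            self.phenotype[mask],
            list(self.variants.values()),
            {v: g[mask] for v, g in self._genotypes.items()},
            {k: v[mask] for k, v in self._covariates.items()},
            None if self.age is None else self.age[mask],
            [sid for sid, m in zip(self.subject_ids, mask) if m],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        if self.variants != other.variants or self.subject_ids != other.subject_ids:
            return False
        if not np.array_equal(self.phenotype, other.phenotype):
            return False
        if set(self._genotypes) != set(other._genotypes):
            return False
        for v in self._genotypes:
            if not np.array_equal(self._genotypes[v], other._genotypes[v]):
                return False
        if set(self._covariates) != set(other._covariates):
            return False
        for k in self._covariates:
            if not np.array_equal(
                self._covariates[k], other._covariates[k], equal_nan=True
            ):
                return False
        if (self.age is None) != (other.age is None):
            return False
        if self.age is not None and not np.array_equal(self.age, other.age, equal_nan=True):
            return False
        return True

    def __repr__(self) -> str:
        return (
            f"CohortTable({self.n_cases} cases / {self.n_controls} controls, "
            f"{len(self.variants)} variants, {len(self._covariates)} covariates)"
        )


@dataclass
class GenotypeCountTable:
    """2x3 phenotype-by-genotype counts for one variant.

    ``counts[0]`` are cases, ``counts[1]`` controls; columns are 0/1/2
    copies of the alternate allele.  Missing calls are excluded, so row
    totals may fall below the cohort case/control totals.
    """

    variant_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 3):
            raise ValueError("counts must be 2x3")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def cases(self) -> np.ndarray:
        return self.counts[0]

    @property
    def controls(self) -> np.ndarray:
        return self.counts[1]

    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class TwoByTwo:
    """2x2 count table: a/b exposed/unexposed cases, c/d likewise controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("2x2 counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("2x2 table is all zero")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    def swapped(self) -> "TwoByTwo":
        """Exposure-reversed table (odds ratio inverts)."""
        return TwoByTwo(self.b, self.a, self.d, self.c)


# ---------------------------------------------------------------------------
# aggregation


def genotype_counts(cohort: CohortTable, variant_id: str) -> GenotypeCountTable:
    """Tabulate a variant's calls by phenotype, excluding missing calls."""
    calls = cohort.calls(variant_id)  # raises KeyError for unknown id
    counts = np.zeros((2, 3), dtype=np.int64)
    for row, pheno in ((0, 1), (1, 0)):
        sub = calls[cohort.phenotype == pheno]
        for g in (0, 1, 2):
            counts[row, g] = int((sub == g).sum())
    return GenotypeCountTable(variant_id, counts)


def collapse(table: GenotypeCountTable, model: str, variant: VariantDef) -> TwoByTwo:
    """Collapse a 2x3 genotype table into a 2x2 genetic contrast.

    ``model="dominant"``: exposed = any copy of the non-reference allele
    classes, unexposed = the reference homozygote.  ``model="recessive"``:
    exposed = the homozygote opposite the reference, unexposed = the other
    two classes.  Counts are conserved: a+b and c+d equal the input row
    totals.
    """
    if model not in ("dominant", "recessive"):
        raise ValueError(f"model must be 'dominant' or 'recessive', got {model!r}")
    ref = variant.reference_call
    opp = 2 - ref
    if model == "dominant":
        exposed = [g for g in (0, 1, 2) if g != ref]
    else:
        exposed = [opp]
    unexposed = [g for g in (0, 1, 2) if g not in exposed]
    a = int(table.cases[exposed].sum())
    b = int(table.cases[unexposed].sum())
    c = int(table.controls[exposed].sum())
    d = int(table.controls[unexposed].sum())
    return TwoByTwo(a, b, c, d)


def crosstab_covariate(
    cohort: CohortTable, covariate: str, on_missing: str = "exclude"
) -> TwoByTwo:
    """2x2 case-control table of a binary covariate.

    ``on_missing="exclude"`` drops subjects with a missing value (the
    default, mirroring per-test complete-case analysis); ``"error"`` raises.
    """
    vals = cohort.covariate(covariate)
    miss = np.isnan(vals)
    if miss.any():
        if on_missing == "error":
            raise ValueError(
                f"covariate {covariate!r} missing for {int(miss.sum())} subjects"
            )
        if on_missing != "exclude":
            raise ValueError("on_missing must be 'exclude' or 'error'")
    keep = ~miss
    y = cohort.phenotype[keep]
    x = vals[keep]
    return TwoByTwo(
        a=int(((y == 1) & (x == 1)).sum()),
        b=int(((y == 1) & (x == 0)).sum()),
        c=int(((y == 0) & (x == 1)).sum()),
        d=int(((y == 0) & (x == 0)).sum()),
    )


# ---------------------------------------------------------------------------
# I/O


@dataclass
class CohortSchema:
    """Column mapping for reading/writing subject tables.

    ``genotype_columns`` maps variant id -> column name (defaults to the
    variant id itself); covariate columns are taken verbatim.
    """

    variants: list[VariantDef]
    phenotype_column: str = "phenotype"
    case_label: str = "1"
    control_label: str = "0"
    covariate_columns: list[str] = field(default_factory=list)
    genotype_columns: dict[str, str] = field(default_factory=dict)
    age_column: str | None = "age"
    id_column: str | None = "subject_id"
    missing_token: str = "NA"

    def column_for(self, variant_id: str) -> str:
        return self.genotype_columns.get(variant_id, variant_id)

    @classmethod
    def from_file(cls, path: str | Path) -> "CohortSchema":
        """Load a schema from YAML or JSON; variants are listed as mappings
        with keys id/allele_ref/allele_alt[/reference_genotype]."""
        text = Path(path).read_text()
        raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        variants = [VariantDef(**v) for v in raw.pop("variants")]
        return cls(variants=variants, **raw)


def read_cohort(path: str | Path, schema: CohortSchema) -> CohortTable:
    """Read a delimited subject table (comma or tab, one header row).

    Unparseable genotype tokens become missing calls; phenotype labels
    outside the schema's case/control labels are a hard error naming the
    offending row.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    if schema.phenotype_column not in df.columns:
        raise ValueError(
            f"mandatory phenotype column {schema.phenotype_column!r} not found "
            f"(columns: {list(df.columns)})"
        )
    pheno_raw = df[schema.phenotype_column].str.strip()
    phenotype = np.empty(len(df), dtype=np.int8)
    for i, label in enumerate(pheno_raw):
        if label == str(schema.case_label):
            phenotype[i] = 1
        elif label == str(schema.control_label):
            phenotype[i] = 0
        else:
            raise ValueError(
                f"row {i}: phenotype label {label!r} is neither case "
                f"({schema.case_label!r}) nor control ({schema.control_label!r})"
            )
    genotypes = {}
    for var in schema.variants:
        col = schema.column_for(var.id)
        if col in df.columns:
            genotypes[var.id] = np.array(
                [var.parse_call(t, schema.missing_token) for t in df[col]],
                dtype=np.int8,
            )
        else:
            genotypes[var.id] = np.full(len(df), MISSING, dtype=np.int8)
    covariates = {}
    for name in schema.covariate_columns:
        if name not in df.columns:
            raise ValueError(f"covariate column {name!r} not found")
        vals = np.full(len(df), np.nan)
        for i, t in enumerate(df[name]):
            t = t.strip()
            if t in ("0", "1"):
                vals[i] = float(t)
            elif t not in (schema.missing_token, ""):
                raise ValueError(f"row {i}: covariate {name!r} value {t!r} not binary")
        covariates[name] = vals
    age = None
    if schema.age_column and schema.age_column in df.columns:
        age = np.array(
            [
                float(t) if t.strip() not in (schema.missing_token, "") else np.nan
                for t in df[schema.age_column]
            ]
        )
    ids = None
    if schema.id_column and schema.id_column in df.columns:
        ids = list(df[schema.id_column])
    return CohortTable(phenotype, schema.variants, genotypes, covariates, age, ids)


def write_cohort(cohort: CohortTable, path: str | Path, schema: CohortSchema) -> None:
    """Write a cohort as a CSV readable back by :func:`read_cohort`."""
    data: dict[str, list] = {}
    if schema.id_column:
        data[schema.id_column] = cohort.subject_ids
    data[schema.phenotype_column] = [
        str(schema.case_label) if p == 1 else str(schema.control_label)
        for p in cohort.phenotype
    ]
    for var in schema.variants:
        calls = cohort.calls(var.id)
        data[schema.column_for(var.id)] = [
            schema.missing_token if g == MISSING else var.genotype_label(int(g))
            for g in calls
        ]
    for name in cohort.covariate_names:
        vals = cohort.covariate(name)
        data[name] = [
            schema.missing_token if np.isnan(v) else str(int(v)) for v in vals
        ]
    if cohort.age is not None and schema.age_column:
        data[schema.age_column] = [
            schema.missing_token if np.isnan(v) else repr(float(v)) for v in cohort.age
        ]
    pd.DataFrame(data).to_csv(path, index=False)
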