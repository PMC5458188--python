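"""Published summary tables of the ARID1B / hepatocellular-carcinoma
case-control study (611 cases, 614 cancer-free controls, Southern Chinese
population) and helpers that expand those counts into cohorts.

Three promoter-region variants were genotyped: rs73013281 C>T,
rs167007 A>G and rs9397984 C>T.  The odds-ratio baseline for rs73013281
is the CC homozygote even though T is the majority allele in this
population, so the baseline is declared explicitly on each variant.

Per-subject covariate data were never deposited, only the marginal and a
few joint count tables; the builders here therefore reconstruct cohorts
that reproduce exactly those published margins.  Joint distributions
beyond the published tables are not recoverable — cohorts built from one
table are valid only for statistics of that table.
"""

from __future__ import annotations

import numpy as np

from .cohort import MISSING, CohortTable, GenotypeCountTable, TwoByTwo, VariantDef

__all__ = [
    "study_variants",
    "covariate_tables",
    "genotype_tables",
    "stratified_joint_counts",
    "cohort_from_genotype_tables",
    "cohort_from_two_by_two",
    "cohort_from_joint_counts",
]

N_CASES = 611
N_CONTROLS = 614


def study_variants() -> dict[str, VariantDef]:
    """The three genotyped variants with their odds-ratio baselines.

    rs73013281: CT/TT contrasted against CC (baseline = reference
    homozygote).  rs167007: GG against AA+AG; rs9397984: TT against CC+CT
    (baseline = reference homozygote, the collapsed contrast is the
    recessive coding for the alternate allele).
    """
    return {
        "rs73013281": VariantDef("rs73013281", "C", "T", "ref_hom"),
        "rs167007": VariantDef("rs167007", "A", "G", "ref_hom"),
        "rs9397984": VariantDef("rs9397984", "C", "T", "ref_hom"),
    }


def covariate_tables() -> dict[str, TwoByTwo]:
    """Case-control 2x2 tables of the binary subject characteristics.

    Exposure orientation: smoking/drinking = ever, physical_activity =
    inactive, hbsag = positive, family_history = yes, gender = male.
    """
    return {
        "gender": TwoByTwo(a=532, b=79, c=530, d=84),
        "smoking": TwoByTwo(a=417, b=194, c=348, d=266),
        "drinking": TwoByTwo(a=343, b=268, c=275, d=339),
        "physical_activity": TwoByTwo(a=391, b=220, c=323, d=291),
        "hbsag": TwoByTwo(a=454, b=157, c=107, d=507),
        "family_history": TwoByTwo(a=85, b=526, c=23, d=591),
    }


def genotype_tables() -> dict[str, GenotypeCountTable]:
    """Published 2x3 genotype distributions (cases row 0, controls row 1;
    columns 0/1/2 copies of the alternate allele).  Row totals fall one
    or two short of 611/614 because of sub-100% genotyping call rates."""
    return {
        "rs73013281": GenotypeCountTable(
            "rs73013281", np.array([[44, 240, 325], [67, 236, 310]])
        ),
        "rs167007": GenotypeCountTable(
            "rs167007", np.array([[6, 83, 522], [3, 87, 520]])
        ),
        "rs9397984": GenotypeCountTable(
            "rs9397984", np.array([[4, 70, 536], [2, 79, 530]])
        ),
    }


def stratified_joint_counts() -> dict[str, dict]:
    """Published rs73013281 carrier (CT/TT) vs CC counts by stratum of
    each lifestyle factor: {exposure: {stratum_value: ((case_ref,
    case_carrier), (ctrl_ref, ctrl_carrier))}} with stratum_value the
    covariate level (1 = exposed orientation of :func:`covariate_tables`)."""
    return {
        "smoking": {0: ((17, 177), (25, 240)), 1: ((27, 388), (42, 306))},
        "drinking": {0: ((19, 249), (37, 302)), 1: ((25, 316), (30, 244))},
        # physical_activity: 1 = inactive, 0 = active
        "physical_activity": {1: ((24, 365), (39, 284)), 0: ((20, 200), (28, 262))},
        "hbsag": {0: ((8, 149), (56, 450)), 1: ((36, 416), (11, 96))},
        "family_history": {0: ((38, 486), (64, 526)), 1: ((6, 79), (3, 20))},
    }


# ---------------------------------------------------------------------------
# cohort reconstruction from counts


def cohort_from_genotype_tables(
    tables: dict[str, GenotypeCountTable] | None = None,
    n_cases: int = N_CASES,
    n_controls: int = N_CONTROLS,
) -> CohortTable:
    """Cohort whose per-variant genotype tabulations reproduce the given
    count tables exactly.

    Genotypes are assigned variant-by-variant in blocks, so the
    cross-variant joint distribution is arbitrary; subjects beyond a
    table's row total carry a missing call (sub-100% call rate).  Valid
    for all single-variant statistics.
    """
    variants = study_variants()
    if tables is None:
        tables = genotype_tables()
    phenotype = np.concatenate(
        [np.ones(n_cases, dtype=np.int8), np.zeros(n_controls, dtype=np.int8)]
    )
    genotypes = {}
    for vid, tab in tables.items():
        if vid not in variants:
            variants[vid] = VariantDef(vid, "A", "B")
        calls = np.full(n_cases + n_controls, MISSING, dtype=np.int8)
        for row, offset, total in ((0, 0, n_cases), (1, n_cases, n_controls)):
            if tab.counts[row].sum() > total:
                raise ValueError(f"{vid}: counts exceed group size")
            pos = offset
            for g in (0, 1, 2):
                k = int(tab.counts[row, g])
                calls[pos : pos + k] = g
                pos += k
        genotypes[vid] = calls
    return CohortTable(
        phenotype, [variants[v] for v in tables], genotypes
    )


def cohort_from_two_by_two(t: TwoByTwo, name: str = "exposure") -> CohortTable:
    """Cohort with one binary covariate reproducing a 2x2 table."""
    phenotype = np.concatenate(
        [np.ones(t.a + t.b, dtype=np.int8), np.zeros(t.c + t.d, dtype=np.int8)]
    )
    vals = np.concatenate(
        [np.ones(t.a), np.zeros(t.b), np.ones(t.c), np.zeros(t.d)]
    )
    return CohortTable(phenotype, [], {}, {name: vals})


def cohort_from_joint_counts(
    variant: VariantDef,
    exposure: str,
    cells: dict[int, tuple[tuple[int, int], tuple[int, int]]],
) -> CohortTable:
    """Cohort with one variant and one binary covariate reproducing
    published genotype-by-exposure-by-phenotype counts.

    ``cells[e] = ((case_ref, case_carrier), (ctrl_ref, ctrl_carrier))``
    for exposure level ``e``.  Carriers are encoded as heterozygotes, so
    the dominant collapse reproduces the carrier counts exactly.
    """
    pheno, geno, expo = [], [], []
    for e, ((case_ref, case_car), (ctrl_ref, ctrl_car)) in cells.items():
        for y, n_ref, n_car in ((1, case_ref, case_car), (0, ctrl_ref, ctrl_car)):
            ref_call = variant.reference_call
            pheno.extend([y] * (n_ref + n_car))
            geno.extend([ref_call] * n_ref + [1] * n_car)
            expo.extend([float(e)] * (n_ref + n_car))
    order = np.argsort(np.asarray(pheno) == 0, kind="stable")  # cases first
    pheno = np.asarray(pheno, dtype=np.int8)[order]
    geno = np.asarray(geno, dtype=np.int8)[order]
    expo = np.asarray(expo, dtype=float)[order]
    return CohortTable(pheno, [variant], {variant.id: geno}, {exposure: expo})
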