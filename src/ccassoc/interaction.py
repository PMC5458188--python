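"""Gene-environment interaction: stratified odds ratios, multiplicative
interaction via the logistic product term, and additive interaction via
the relative excess risk due to interaction (RERI) with a stratified
nonparametric bootstrap test.

The genetic factor G is a collapsed (binary) genetic contrast, by
default the dominant carrier contrast; the environment E a binary
covariate.  The joint-exposure model codes three indicators — G only,
E only, both — against the doubly-unexposed reference cell, so

    RERI = OR11 - OR10 - OR01 + 1

is zero exactly when the OR-scale excess risks add.  The attributable
proportion AP = RERI / OR11 and synergy index
S = (OR11 - 1) / (OR10 + OR01 - 2) are reported alongside; RERI drives
the additive p-value.

The bootstrap resamples subjects with replacement *within* phenotype
groups (cases and controls separately): the case-control design fixes
those margins by construction, so resampling must respect them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .association import (
    GeneticModelCoding,
    LogisticFit,
    ORResult,
    crude_or,
    fit_logistic,
)
from .cohort import MISSING, CohortTable, TwoByTwo, VariantDef

__all__ = [
    "JOINT_TERMS",
    "joint_exposure_design",
    "InteractionResult",
    "stratified_ors",
    "multiplicative_interaction",
    "reri",
    "attributable_proportion",
    "synergy_index",
    "additive_interaction_bootstrap",
    "pairwise_interaction",
]

JOINT_TERMS = ("g_only", "e_only", "g_and_e")


def joint_exposure_design(g: np.ndarray, e: np.ndarray):
    """Three joint-exposure indicator columns against the (G=0, E=0) cell.

    Exactly one indicator is 1 for every subject outside the reference
    cell.  Returns (n x 3 matrix, term names).
    """
    g = np.asarray(g, dtype=bool)
    e = np.asarray(e, dtype=bool)
    cols = np.column_stack([g & ~e, ~g & e, g & e]).astype(float)
    return cols, list(JOINT_TERMS)


@dataclass
class InteractionResult:
    """Full pairwise G x E analysis for one variant/exposure pair."""

    variant_id: str
    exposure: str
    stratum_ors: Mapping[object, ORResult]
    or_interaction: float
    p_multiplicative: float
    reri_point: float
    reri_ci: tuple[float, float]
    p_additive: float
    ap: float
    synergy: float
    n_boot: int
    seed: int | None
    n_boot_failed: int = 0
    covariates: tuple[str, ...] = ()


def _gxe_arrays(cohort, variant, coding, exposure, covariates):
    """Complete-case (y, G binary, E binary, covariate columns).

    The exposure/stratifier is dropped from the adjustment list: it is
    already a model term (or constant within a stratum).
    """
    if coding.name not in ("dominant", "recessive"):
        raise ValueError(
            "interaction analyses need a collapsed (binary) genetic contrast; "
            f"got {coding.name!r}"
        )
    calls = cohort.calls(variant.id)
    e = cohort.covariate(exposure)
    mask = (calls != MISSING) & ~np.isnan(e)
    covariates = [c for c in covariates if c != exposure]
    covs = []
    for name in covariates:
        arr = cohort.age if name == "age" else cohort.covariate(name)
        covs.append(arr)
        mask &= ~np.isnan(arr)
    gcol = coding.design(calls[mask], variant)[0][:, 0]
    return (
        cohort.phenotype[mask].astype(float),
        gcol,
        e[mask],
        [arr[mask] for arr in covs],
        tuple(covariates),
    )


def stratified_ors(
    cohort: CohortTable,
    variant: VariantDef,
    coding: GeneticModelCoding,
    stratifier: str,
    covariates=(),
) -> dict[object, ORResult]:
    """Collapsed-contrast OR within each level of a binary stratifier.

    Crude (cross-product with Woolf CI) when ``covariates`` is empty,
    otherwise covariate-adjusted via logistic regression.  A stratum with
    a zero cell falls back to the Haldane-corrected crude OR (flagged).
    """
    y, g, s, covs, covariates = _gxe_arrays(cohort, variant, coding, stratifier, covariates)
    out: dict[object, ORResult] = {}
    for level in sorted(int(v) for v in np.unique(s)):
        m = s == level
        t = TwoByTwo(
            a=int(((y == 1) & (g == 1) & m).sum()),
            b=int(((y == 1) & (g == 0) & m).sum()),
            c=int(((y == 0) & (g == 1) & m).sum()),
            d=int(((y == 0) & (g == 0) & m).sum()),
        )
        zero_cell = min(t.a, t.b, t.c, t.d) == 0
        if covariates and not zero_cell:
            X = np.column_stack([g[m], *[cv[m] for cv in covs]])
            fit = fit_logistic(y[m], X, terms=["g", *covariates])
            if fit.converged:
                out[level] = fit.or_result(
                    "g",
                    contrast_label=f"{stratifier}={level}",
                    adjusted=True,
                    covariates=tuple(covariates),
                    counts=t,
                )
                continue
            import warnings

            warnings.warn(
                f"stratum {stratifier}={level}: adjusted fit failed; "
                "reporting crude OR"
            )
        elif covariates and zero_cell:
            import warnings

            warnings.warn(
                f"stratum {stratifier}={level}: zero cell; adjusted fit "
                "skipped, Haldane-corrected crude OR reported"
            )
        out[level] = crude_or(t, contrast_label=f"{stratifier}={level}")
    return out


def multiplicative_interaction(
    cohort: CohortTable,
    variant: VariantDef,
    coding: GeneticModelCoding,
    exposure: str,
    covariates=(),
) -> tuple[float, float, LogisticFit]:
    """Product-term test of multiplicative interaction.

    Fits logit P(case) ~ G + E + covariates + G*E and returns
    (interaction OR = exp(product coefficient), two-sided Wald p, fit).
    On a saturated 2x2x2 table the interaction OR equals the ratio of the
    stratum cross-product ORs.
    """
    y, g, e, covs, covariates = _gxe_arrays(cohort, variant, coding, exposure, covariates)
    X = np.column_stack([g, e, *covs, g * e])
    terms = ["g", "e", *covariates, "g_x_e"]
    fit = fit_logistic(y, X, terms=terms)
    if not fit.converged:
        raise RuntimeError(
            f"interaction model for {variant.id} x {exposure} did not converge"
        )
    return float(np.exp(fit.coef("g_x_e"))), fit.wald_p("g_x_e"), fit


def reri(fit: LogisticFit, terms=JOINT_TERMS) -> float:
    """Relative excess risk due to interaction from a joint-exposure fit.

    RERI = OR11 - OR10 - OR01 + 1 with the ORs the exponentiated
    coefficients of the (G only, E only, joint) indicators.
    """
    if not fit.converged:
        raise ValueError("RERI requires a converged fit")
    try:
        or10, or01, or11 = (np.exp(fit.coef(t)) for t in terms)
    except ValueError as exc:
        raise ValueError(f"joint-exposure term missing from fit: {exc}") from exc
    return float(or11 - or10 - or01 + 1.0)


def attributable_proportion(or10: float, or01: float, or11: float) -> float:
    """AP = RERI / OR11: proportion of the joint-cell odds ratio
    attributable to interaction."""
    return (or11 - or10 - or01 + 1.0) / or11


def synergy_index(or10: float, or01: float, or11: float) -> float:
    """S = (OR11 - 1) / (OR10 + OR01 - 2); 1 under exact additivity."""
    return (or11 - 1.0) / (or10 + or01 - 2.0)


def _cell_ors(case_counts, ctrl_counts):
    """Cross-product ORs of the three non-reference joint-exposure cells.

    Counts are length-4 vectors over cells (00, 10, 01, 11); adds 0.5 to
    every cell if any involved cell is zero (Haldane).  Supports leading
    batch dimensions for vectorised bootstrap resamples.
    """
    cc = np.asarray(case_counts, dtype=float)
    nn = np.asarray(ctrl_counts, dtype=float)
    any_zero = (np.minimum(cc, nn).min(axis=-1) == 0)[..., None]
    cc = cc + 0.5 * any_zero
    nn = nn + 0.5 * any_zero
    ors = (cc[..., 1:] * nn[..., :1]) / (cc[..., :1] * nn[..., 1:])
    return ors  # (..., 3): OR10, OR01, OR11


def _joint_cells(y, g, e):
    idx = (g > 0).astype(int) + 2 * (e > 0).astype(int)  # 0:00 1:10 2:01 3:11
    case = np.bincount(idx[y == 1], minlength=4)
    ctrl = np.bincount(idx[y == 0], minlength=4)
    return idx, case, ctrl


def additive_interaction_bootstrap(
    cohort: CohortTable,
    variant: VariantDef,
    coding: GeneticModelCoding,
    exposure: str,
    covariates=(),
    n_boot: int = 10_000,
    seed: int | None = None,
    max_fail_frac: float = 0.01,
):
    """Bootstrap test of departure from additivity (RERI != 0).

    Subjects are resampled with replacement within phenotype groups
    (preserving the case and control totals), RERI recomputed on each
    resample, a percentile CI taken, and

        p_additive = 2 * min(frac(RERI* <= 0), frac(RERI* > 0))

    clipped to [2/n_boot, 1].  Deterministic given the seed.  Returns
    (reri_point, (ci_low, ci_high), p_additive, n_failed, boot_reris).
    """
    if seed is None:
        raise ValueError("seed is mandatory for the additive-interaction bootstrap")
    y, g, e, covs, covariates = _gxe_arrays(cohort, variant, coding, exposure, covariates)
    rng = np.random.default_rng(seed)
    idx, case_cells, ctrl_cells = _joint_cells(y, g, e)
    n_failed = 0
    if not covariates:
        # Crude joint-exposure ORs are saturated-model cross-products, so
        # within-stratum subject resampling reduces to multinomial cell
        # resampling — exact, and vectorised over all resamples.
        ors = _cell_ors(case_cells, ctrl_cells)
        point = float(ors[2] - ors[0] - ors[1] + 1.0)
        n_cases, n_controls = int(case_cells.sum()), int(ctrl_cells.sum())
        boot_case = rng.multinomial(n_cases, case_cells / n_cases, size=n_boot)
        boot_ctrl = rng.multinomial(n_controls, ctrl_cells / n_controls, size=n_boot)
        bors = _cell_ors(boot_case, boot_ctrl)
        boot = bors[:, 2] - bors[:, 0] - bors[:, 1] + 1.0
    else:
        X = np.column_stack(
            [joint_exposure_design(g, e)[0], *covs]
        )
        terms = [*JOINT_TERMS, *covariates]
        fit = fit_logistic(y, X, terms=terms)
        if not fit.converged:
            raise RuntimeError("joint-exposure model did not converge on observed data")
        point = reri(fit)
        cases = np.flatnonzero(y == 1)
        ctrls = np.flatnonzero(y == 0)
        boot = np.empty(n_boot)
        for b in range(n_boot):
            take = np.concatenate(
                [
                    rng.choice(cases, size=cases.size, replace=True),
                    rng.choice(ctrls, size=ctrls.size, replace=True),
                ]
            )
            try:
                f = fit_logistic(y[take], X[take], terms=terms)
                if not f.converged:
                    raise RuntimeError
                boot[b] = reri(f)
            except (RuntimeError, ValueError, np.linalg.LinAlgError):
                boot[b] = np.nan
                n_failed += 1
        if n_failed > max_fail_frac * n_boot:
            raise RuntimeError(
                f"{n_failed}/{n_boot} bootstrap resamples failed to converge; "
                "additive-interaction p-value unreliable"
            )
        boot = boot[~np.isnan(boot)]
    ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
    frac_le = float((boot <= 0).mean())
    frac_gt = float((boot > 0).mean())
    p = 2.0 * min(frac_le, frac_gt)
    p = float(np.clip(p, 2.0 / n_boot, 1.0))
    return point, ci, p, n_failed, boot


def pairwise_interaction(
    cohort: CohortTable,
    variant: VariantDef,
    exposure: str,
    coding: GeneticModelCoding | None = None,
    covariates=(),
    n_boot: int = 10_000,
    seed: int | None = None,
) -> InteractionResult:
    """Complete pairwise G x E analysis: stratified ORs, multiplicative
    product-term p, and the RERI bootstrap additive p, in one call."""
    if coding is None:
        coding = GeneticModelCoding("dominant")
    strat = stratified_ors(cohort, variant, coding, exposure, covariates)
    or_int, p_mult, _ = multiplicative_interaction(
        cohort, variant, coding, exposure, covariates
    )
    point, ci, p_add, n_failed, _ = additive_interaction_bootstrap(
        cohort, variant, coding, exposure, covariates, n_boot=n_boot, seed=seed
    )
    y, g, e, _, _ = _gxe_arrays(cohort, variant, coding, exposure, covariates)
    _, case_cells, ctrl_cells = _joint_cells(y, g, e)
    or10, or01, or11 = _cell_ors(case_cells, ctrl_cells)
    return InteractionResult(
        variant_id=variant.id,
        exposure=exposure,
        stratum_ors=strat,
        or_interaction=or_int,
        p_multiplicative=p_mult,
        reri_point=point,
        reri_ci=ci,
        p_additive=p_add,
        ap=attributable_proportion(or10, or01, or11),
        synergy=synergy_index(or10, or01, or11),
        n_boot=n_boot,
        seed=seed,
        n_boot_failed=n_failed,
        covariates=tuple(covariates),
    )
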