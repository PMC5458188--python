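"""Single-table association statistics.

Pearson chi-square on r x c count tables (no continuity correction),
Hardy-Weinberg goodness-of-fit, crude odds ratios with Woolf confidence
intervals, a maximum-likelihood logistic fitter (IRLS), adjusted odds
ratios under the four standard genetic-model codings, and AIC-based
genetic-model selection.

All confidence intervals are 95% two-sided with z = 1.959964; all
p-values two-sided.  Zero cells in a 2x2 table trigger the
Haldane-Anscombe +0.5 correction and flag the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import MISSING, CohortTable, TwoByTwo, VariantDef, genotype_counts

Z95 = 1.959964

__all__ = [
    "Z95",
    "ChiSquareResult",
    "ORResult",
    "HWEResult",
    "LogisticFit",
    "GeneticModelCoding",
    "GENETIC_MODELS",
    "pearson_chi2",
    "crude_or",
    "hwe_test",
    "fit_logistic",
    "adjusted_or",
    "select_genetic_model",
    "ModelFit",
]


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


@dataclass
class ORResult:
    """An odds ratio with Woolf-type 95% CI and two-sided Wald p-value."""

    or_point: float
    ci_low: float
    ci_high: float
    p_value: float
    contrast_label: str = ""
    adjusted: bool = False
    covariates: tuple[str, ...] = ()
    haldane_corrected: bool = False
    counts: TwoByTwo | None = None


@dataclass
class HWEResult:
    """Goodness-of-fit test of genotype counts against p^2 / 2pq / q^2."""

    allele_freq: float  # alt-allele frequency estimate
    expected_counts: np.ndarray
    statistic: float
    df: int
    p_value: float
    monomorphic: bool = False


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic regression fit.

    ``terms`` names the design columns (including "intercept"); ``vcov``
    is the inverse observed information.  ``converged`` must be checked
    before any downstream use of the coefficients.
    """

    terms: tuple[str, ...]
    beta: np.ndarray
    vcov: np.ndarray
    loglik: float
    converged: bool
    n_used: int
    n_iter: int = 0

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))

    def coef(self, term: str) -> float:
        return float(self.beta[self.terms.index(term)])

    def wald_p(self, term: str) -> float:
        i = self.terms.index(term)
        z = self.beta[i] / np.sqrt(self.vcov[i, i])
        return float(2.0 * stats.norm.sf(abs(z)))

    @property
    def aic(self) -> float:
        return float(2 * len(self.terms) - 2 * self.loglik)

    def or_result(self, term: str, z: float = Z95, **kw) -> ORResult:
        """Odds ratio, Wald CI and p for one coefficient."""
        i = self.terms.index(term)
        b = float(self.beta[i])
        se = float(np.sqrt(self.vcov[i, i]))
        return ORResult(
            or_point=float(np.exp(b)),
            ci_low=float(np.exp(b - z * se)),
            ci_high=float(np.exp(b + z * se)),
            p_value=float(2.0 * stats.norm.sf(abs(b / se))),
            **kw,
        )


# ---------------------------------------------------------------------------
# contingency statistics


def pearson_chi2(table: np.ndarray | TwoByTwo) -> ChiSquareResult:
    """Pearson chi-square on an r x c count table, without continuity
    correction, expected counts from the product of the margins."""
    if isinstance(table, TwoByTwo):
        table = table.as_array()
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row_tot = obs.sum(axis=1)
    col_tot = obs.sum(axis=0)
    for i, t in enumerate(row_tot):
        if t == 0:
            raise ValueError(f"degenerate table: row {i} has zero total")
    for j, t in enumerate(col_tot):
        if t == 0:
            raise ValueError(f"degenerate table: column {j} has zero total")
    stat, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return ChiSquareResult(statistic=float(stat), df=int(df), p_value=float(p))


def crude_or(t: TwoByTwo, z: float = Z95, **kw) -> ORResult:
    """Cross-product odds ratio ad/bc with Woolf CI and Wald p.

    Any zero cell triggers the Haldane-Anscombe correction (+0.5 to all
    four cells) and flags the result.
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    haldane = min(a, b, c, d) == 0
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ORResult(
        or_point=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
        p_value=float(2.0 * stats.norm.sf(abs(log_or / se))),
        haldane_corrected=haldane,
        counts=t,
        **kw,
    )


def hwe_test(control_counts) -> HWEResult:
    """Hardy-Weinberg goodness-of-fit chi-square (1 df, asymptotic).

    ``control_counts`` are genotype counts (n0, n1, n2) as copies of the
    alternate allele.  A monomorphic sample returns statistic 0 with the
    ``monomorphic`` flag set.
    """
    n0, n1, n2 = (int(x) for x in control_counts)
    n = n0 + n1 + n2
    if n <= 0:
        raise ValueError("empty genotype counts")
    p_alt = (2 * n2 + n1) / (2 * n)
    q = 1.0 - p_alt
    expected = np.array([q * q * n, 2 * p_alt * q * n, p_alt * p_alt * n])
    if p_alt in (0.0, 1.0):
        return HWEResult(p_alt, expected, 0.0, 1, 1.0, monomorphic=True)
    obs = np.array([n0, n1, n2], dtype=float)
    statistic = float(((obs - expected) ** 2 / expected).sum())
    return HWEResult(
        allele_freq=p_alt,
        expected_counts=expected,
        statistic=statistic,
        df=1,
        p_value=float(stats.chi2.sf(statistic, 1)),
    )


def hwe_exact_test(control_counts) -> float:
    """Exact Hardy-Weinberg p-value (conditional on allele counts;
    mid-free, sum of probabilities <= observed). Offered as an option;
    the asymptotic chi-square is the default everywhere else."""
    n0, n1, n2 = (int(x) for x in control_counts)
    n = n0 + n1 + n2
    n_alt = 2 * n2 + n1
    n_ref = 2 * n0 + n1
    rare = min(n_alt, n_ref)
    # enumerate heterozygote counts with the same parity as `rare`
    from math import lgamma

    def log_prob(nh):
        n_hom_rare = (rare - nh) // 2
        n_hom_com = (2 * n - rare - nh) // 2
        return (
            nh * np.log(2)
            + lgamma(n + 1)
            - lgamma(n_hom_rare + 1)
            - lgamma(nh + 1)
            - lgamma(n_hom_com + 1)
            + lgamma(rare + 1)
            + lgamma(2 * n - rare + 1)
            - lgamma(2 * n + 1)
        )

    hets = range(rare % 2, rare + 1, 2)
    logs = np.array([log_prob(nh) for nh in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs_het = n1
    p_obs = probs[list(hets).index(obs_het)]
    return float(probs[probs <= p_obs + 1e-12].sum())


# ---------------------------------------------------------------------------
# logistic regression (IRLS)


def fit_logistic(
    y: np.ndarray,
    X: np.ndarray,
    terms: tuple[str, ...] | list[str] | None = None,
    add_intercept: bool = True,
    max_iter: int = 100,
    tol_beta: float = 1e-8,
    tol_loglik: float = 1e-10,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by iteratively reweighted
    least squares.

    Convergence when max\\|step\\| < 1e-8 or the log-likelihood change is
    below 1e-10, capped at ``max_iter`` iterations.  Separation is flagged
    (any coefficient beyond 15 on the predictor-standardised scale at the
    cap) and the fit returned non-converged rather than silently trusted.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    if add_intercept:
        X = np.column_stack([np.ones(y.size), X])
        if terms is not None:
            terms = ["intercept", *terms]
    if terms is None:
        terms = [f"x{j}" for j in range(X.shape[1])]
        if add_intercept:
            terms[0] = "intercept"
    terms = tuple(terms)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"n_used ({n}) must exceed number of terms ({k})")
    sd = X.std(axis=0)
    for j in range(1 if add_intercept else 0, k):
        if sd[j] == 0:
            raise ValueError(f"constant non-intercept column {terms[j]!r}")

    beta = np.zeros(k)
    eta = X @ beta
    mu = _expit_clipped(eta)
    ll = _bernoulli_loglik(y, mu)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        # step-halving keeps the likelihood non-decreasing
        new_ll, new_beta, new_mu = -np.inf, beta, mu
        factor = 1.0
        for _ in range(25):
            cand = beta + factor * step
            cand_mu = _expit_clipped(X @ cand)
            cand_ll = _bernoulli_loglik(y, cand_mu)
            if cand_ll >= ll - 1e-12:
                new_ll, new_beta, new_mu = cand_ll, cand, cand_mu
                break
            factor *= 0.5
        if new_ll == -np.inf:  # no improving step
            break
        delta = np.abs(new_beta - beta).max()
        dll = abs(new_ll - ll)
        beta, mu, ll = new_beta, new_mu, new_ll
        if delta < tol_beta or dll < tol_loglik:
            converged = True
            break

    w = mu * (1.0 - mu)
    info = (X * w[:, None]).T @ X
    try:
        vcov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(info)
        converged = False
    if converged:
        scale = np.where(sd > 0, sd, 1.0)
        if np.any(np.abs(beta * scale) > 15.0):
            converged = False  # separation: estimates diverging
    return LogisticFit(
        terms=terms,
        beta=beta,
        vcov=vcov,
        loglik=float(ll),
        converged=converged,
        n_used=n,
        n_iter=it,
    )


def _expit_clipped(eta: np.ndarray) -> np.ndarray:
    from scipy.special import expit

    return np.clip(expit(eta), 1e-12, 1 - 1e-12)


def _bernoulli_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    return float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))


# ---------------------------------------------------------------------------
# genetic-model codings


class GeneticModelCoding:
    """Design-column builder for a genetic model.

    ``codominant`` yields one indicator per non-reference genotype class
    (2 columns); ``dominant``/``recessive`` one indicator; ``additive``
    the 0/1/2 count of non-reference alleles.  The baseline is the
    variant's declared reference homozygote.
    """

    NAMES = ("codominant", "dominant", "recessive", "additive")

    def __init__(self, name: str) -> None:
        if name not in self.NAMES:
            raise ValueError(f"unknown genetic model {name!r}")
        self.name = name

    def __repr__(self) -> str:
        return f"GeneticModelCoding({self.name!r})"

    def design(self, calls: np.ndarray, variant: VariantDef):
        """Columns (n x k) and contrast labels for non-missing calls."""
        calls = np.asarray(calls)
        ref = variant.reference_call
        opp = 2 - ref
        lab = variant.genotype_label
        if self.name == "codominant":
            cols = np.column_stack([(calls == 1), (calls == opp)]).astype(float)
            labels = [f"{lab(1)} vs {lab(ref)}", f"{lab(opp)} vs {lab(ref)}"]
        elif self.name == "dominant":
            cols = (calls != ref).astype(float)[:, None]
            labels = [f"{lab(1)}+{lab(opp)} vs {lab(ref)}"]
        elif self.name == "recessive":
            cols = (calls == opp).astype(float)[:, None]
            labels = [f"{lab(opp)} vs {lab(ref)}+{lab(1)}"]
        else:  # additive
            cols = np.abs(calls - ref).astype(float)[:, None]
            labels = [f"per {lab(opp)[0]} allele"]
        return cols, labels


GENETIC_MODELS = tuple(GeneticModelCoding(n) for n in GeneticModelCoding.NAMES)


def _assemble_design(
    cohort: CohortTable,
    variant: VariantDef,
    coding: GeneticModelCoding,
    covariates,
):
    """Complete-case outcome/design for a genetic model with adjusters.

    Returns (y, X, term names, genetic term names, labels)."""
    calls = cohort.calls(variant.id)
    mask = calls != MISSING
    cov_arrays = []
    for name in covariates:
        arr = cohort.age if name == "age" else cohort.covariate(name)
        if arr is None:
            raise ValueError("cohort has no age data")
        cov_arrays.append(arr)
        mask &= ~np.isnan(arr)
    y = cohort.phenotype[mask].astype(float)
    gcols, labels = coding.design(calls[mask], variant)
    gterms = [f"{variant.id}[{coding.name}:{j}]" for j in range(gcols.shape[1])]
    X = gcols
    terms = list(gterms)
    for name, arr in zip(covariates, cov_arrays):
        X = np.column_stack([X, arr[mask]])
        terms.append(name)
    return y, X, terms, gterms, labels


def adjusted_or(
    cohort: CohortTable,
    variant: VariantDef,
    coding: GeneticModelCoding,
    covariates=(),
    z: float = Z95,
) -> list[ORResult]:
    """Odds ratio(s) for a genetic contrast from a covariate-adjusted
    logistic model, one ORResult per genotype term.

    With ``covariates=()`` this reproduces the crude cross-product OR on
    the same complete-case subject set (saturated-model identity).
    """
    y, X, terms, gterms, labels = _assemble_design(cohort, variant, coding, covariates)
    fit = fit_logistic(y, X, terms=terms)
    if not fit.converged:
        raise RuntimeError(
            f"logistic fit for {variant.id} ({coding.name}) did not converge "
            f"after {fit.n_iter} iterations (possible separation)"
        )
    out = []
    for t, lab in zip(gterms, labels):
        out.append(
            fit.or_result(
                t,
                z=z,
                contrast_label=lab,
                adjusted=bool(covariates),
                covariates=tuple(covariates),
            )
        )
    return out


@dataclass
class ModelFit:
    """One genetic-model fit in a model-selection report."""

    coding: GeneticModelCoding
    fit: LogisticFit
    or_results: list[ORResult]
    aic: float = field(init=False)

    def __post_init__(self) -> None:
        self.aic = self.fit.aic


def select_genetic_model(
    cohort: CohortTable,
    variant: VariantDef,
    covariates=(),
) -> list[ModelFit]:
    """Fit codominant, dominant, recessive and additive models and rank
    by AIC (best first).  Non-converged fits are excluded from the ranking
    with a warning; all converged fits are reported, none discarded."""
    fits: list[ModelFit] = []
    for coding in GENETIC_MODELS:
        y, X, terms, gterms, labels = _assemble_design(
            cohort, variant, coding, covariates
        )
        fit = fit_logistic(y, X, terms=terms)
        if not fit.converged:
            warnings.warn(
                f"{variant.id}: {coding.name} model did not converge; "
                "excluded from AIC ranking"
            )
            continue
        ors = [
            fit.or_result(
                t,
                contrast_label=lab,
                adjusted=bool(covariates),
                covariates=tuple(covariates),
            )
            for t, lab in zip(gterms, labels)
        ]
        fits.append(ModelFit(coding=coding, fit=fit, or_results=ors))
    fits.sort(key=lambda m: m.aic)
    return fits
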