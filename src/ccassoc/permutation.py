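"""Empirical p-values by phenotype-label permutation.

Case/control labels are shuffled uniformly; genotypes and covariates
travel with the subject, so the genotype-covariate joint distribution is
preserved and exchangeability holds under the global null of no
phenotype association.  All requested tests share one permutation
stream, so the resulting empirical p-values account for the correlation
among linked variants.  The add-one rule (r+1)/(B+1) keeps empirical
p-values strictly positive.

The per-permutation statistic family is fixed per test: without
adjustment covariates it is the classic crude score test for the coding
(Pearson chi-square for dominant/recessive/codominant contrasts,
Cochran-Armitage trend for additive), which vectorises across the whole
permutation stream; with covariates each permutation refits the logistic
model and uses the Wald test of the genetic term(s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .association import GeneticModelCoding, fit_logistic
from .cohort import MISSING, CohortTable, VariantDef

__all__ = ["PermutationResult", "PermutationTest", "permutation_pvalues"]


@dataclass
class PermutationResult:
    test_id: str
    observed_p: float
    empirical_p: float
    n_perm: int
    seed: int
    n_as_extreme: int


@dataclass
class PermutationTest:
    """One (variant, genetic-model, adjusters) test in the shared stream."""

    variant: VariantDef
    coding: GeneticModelCoding
    covariates: tuple[str, ...] = ()

    @property
    def test_id(self) -> str:
        cov = f"|{','.join(self.covariates)}" if self.covariates else ""
        return f"{self.variant.id}:{self.coding.name}{cov}"


def permutation_pvalues(
    cohort: CohortTable,
    tests: list[PermutationTest],
    n_perm: int = 10_000,
    seed: int | None = None,
    max_fail_frac: float = 0.01,
    return_indices: bool = False,
):
    """Empirical permutation p-values for a list of genetic-model tests.

    One stream of ``n_perm`` uniform phenotype-label shuffles is shared
    by every test; for each test the p-value of its statistic is
    recomputed on every shuffled cohort and
    ``empirical_p = (#{perm p <= observed p} + 1) / (n_perm + 1)``.

    Deterministic given (cohort, tests, n_perm, seed); ``seed`` is
    mandatory.  Aborts if any adjusted test fails to converge in more
    than ``max_fail_frac`` of permutations.
    """
    if seed is None:
        raise ValueError("seed is mandatory for permutation_pvalues")
    rng = np.random.default_rng(seed)
    y = cohort.phenotype.astype(np.int8)
    n = y.size
    perm_idx = np.empty((n_perm, n), dtype=np.int32)
    for b in range(n_perm):
        perm_idx[b] = rng.permutation(n)
    perm_y = y[perm_idx]  # (n_perm, n) shuffled labels

    results = []
    for test in tests:
        obs_p, perm_p = _test_pvalues(cohort, test, y, perm_y, max_fail_frac)
        n_extreme = int((perm_p <= obs_p + 1e-15).sum())
        results.append(
            PermutationResult(
                test_id=test.test_id,
                observed_p=float(obs_p),
                empirical_p=(n_extreme + 1) / (n_perm + 1),
                n_perm=n_perm,
                seed=seed,
                n_as_extreme=n_extreme,
            )
        )
    if return_indices:
        return results, perm_idx
    return results


def _test_pvalues(cohort, test, y, perm_y, max_fail_frac):
    calls = cohort.calls(test.variant.id)
    mask = calls != MISSING
    cov_arrays = []
    for name in test.covariates:
        arr = cohort.age if name == "age" else cohort.covariate(name)
        cov_arrays.append(arr)
        mask &= ~np.isnan(arr)
    g = calls[mask]
    ym = y[mask].astype(float)
    pym = perm_y[:, mask].astype(float)
    if not test.covariates:
        return _crude_pvalues(g, ym, pym, test)
    X = test.coding.design(g, test.variant)[0]
    k_gen = X.shape[1]
    for arr in cov_arrays:
        X = np.column_stack([X, arr[mask]])
    obs_p = _wald_block_p(ym, X, k_gen)
    perm_p = np.empty(pym.shape[0])
    n_fail = 0
    for b in range(pym.shape[0]):
        try:
            perm_p[b] = _wald_block_p(pym[b], X, k_gen)
        except (RuntimeError, ValueError):
            perm_p[b] = np.nan
            n_fail += 1
    if n_fail > max_fail_frac * pym.shape[0]:
        raise RuntimeError(
            f"{test.test_id}: {n_fail}/{pym.shape[0]} permutations failed to "
            "converge; permutation p-values unreliable for this model"
        )
    perm_p = np.where(np.isnan(perm_p), 1.0, perm_p)
    return obs_p, perm_p


def _wald_block_p(y, X, k_gen):
    fit = fit_logistic(y, X)
    if not fit.converged:
        raise RuntimeError("non-converged")
    b = fit.beta[1 : 1 + k_gen]  # genetic terms follow the intercept
    V = fit.vcov[1 : 1 + k_gen, 1 : 1 + k_gen]
    stat = float(b @ np.linalg.solve(V, b))
    return float(stats.chi2.sf(stat, k_gen))


# ---------------------------------------------------------------------------
# vectorised crude score tests


def _crude_pvalues(g, ym, pym, test):
    """Observed and per-permutation p-values for unadjusted tests.

    Degenerate permutations (zero margin) get statistic 0 / p 1.
    """
    name = test.coding.name
    ref = test.variant.reference_call
    if name in ("dominant", "recessive"):
        x = (
            (g != ref) if name == "dominant" else (g == 2 - ref)
        ).astype(float)
        return (
            _chi2_2x2_p(x, ym[None, :])[0],
            _chi2_2x2_p(x, pym),
        )
    if name == "codominant":
        return _chi2_2xk_p(g, ym[None, :])[0], _chi2_2xk_p(g, pym)
    # additive: Cochran-Armitage trend, scores = copies of non-reference allele
    x = np.abs(g - ref).astype(float)
    return _trend_p(x, ym[None, :])[0], _trend_p(x, pym)


def _chi2_2x2_p(x, Y):
    """Vectorised uncorrected 2x2 Pearson chi-square p per label row."""
    N = x.size
    m1 = x.sum()
    n1 = Y.sum(axis=1)
    a = Y @ x
    denom = n1 * (N - n1) * m1 * (N - m1)
    stat = np.zeros(Y.shape[0])
    ok = denom > 0
    stat[ok] = N * (N * a[ok] - n1[ok] * m1) ** 2 / denom[ok]
    return stats.chi2.sf(stat, 1)


def _chi2_2xk_p(g, Y):
    """Vectorised 2xk genotype-table chi-square p per label row."""
    classes = np.unique(g)
    m = np.array([(g == c).sum() for c in classes], dtype=float)
    N = g.size
    n1 = Y.sum(axis=1)
    stat = np.zeros(Y.shape[0])
    for c, mc in zip(classes, m):
        a = Y @ (g == c).astype(float)  # cases in class c
        for case_count, group in ((a, n1), (mc - a, N - n1)):
            E = group * mc / N
            ok = E > 0
            stat[ok] += (case_count[ok] - E[ok]) ** 2 / E[ok]
    df = max(len(classes) - 1, 1)
    p = stats.chi2.sf(stat, df)
    n_margin_ok = (n1 > 0) & (n1 < N)
    return np.where(n_margin_ok, p, 1.0)


def _trend_p(x, Y):
    """Vectorised Cochran-Armitage trend test p per label row."""
    N = x.size
    sx = x.sum()
    sxx = (x * x).sum()
    n1 = Y.sum(axis=1)
    t = Y @ x
    var_num = N * sxx - sx * sx
    denom = n1 * (N - n1) * var_num
    stat = np.zeros(Y.shape[0])
    ok = denom > 0
    stat[ok] = N * (N * t[ok] - n1[ok] * sx) ** 2 / denom[ok]
    return stats.chi2.sf(stat, 1)
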