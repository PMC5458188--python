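"""EM estimation of multi-locus haplotype frequencies from unphased
genotypes, pairwise linkage disequilibrium, and haplotype-level
case-control association.

The E-step distributes each subject's probability mass over the diplotype
pairs compatible with the unphased genotype, proportional to current
haplotype frequencies (2*f_i*f_j for heterozygous pairs, f_i^2 for
homozygous); the M-step re-estimates frequencies from expected haplotype
counts.  The observed-data log-likelihood is non-decreasing at every
iteration and is asserted so.  On phase-unambiguous data (no subject
with more than one heterozygous locus) EM reduces to direct counting.

Subjects with any missing call over the locus block are excluded
(complete-case per block); no imputation inside EM.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .association import ORResult, crude_or
from .cohort import MISSING, TwoByTwo, VariantDef

__all__ = [
    "HaplotypeSet",
    "LDStats",
    "em_haplotypes",
    "pairwise_ld",
    "ld_from_haplotype_freqs",
    "haplotype_association",
    "HaplotypeAssociation",
]


@dataclass
class HaplotypeSet:
    """Estimated haplotype frequency distribution over an ordered locus
    block.  Haplotypes are 0/1 strings (0 = reference allele) unless
    variant definitions were supplied, in which case allele letters."""

    loci: tuple[str, ...]
    haplotypes: tuple[str, ...]
    freqs: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    n_subjects: int = 0
    bits: tuple[tuple[int, ...], ...] = ()  # 0/1 allele codes per haplotype

    def freq(self, haplotype: str) -> float:
        try:
            return float(self.freqs[self.haplotypes.index(haplotype)])
        except ValueError:
            return 0.0

    def as_dict(self) -> dict[str, float]:
        return {h: float(f) for h, f in zip(self.haplotypes, self.freqs)}


@dataclass
class LDStats:
    locus_pair: tuple[str, str]
    D: float
    D_prime: float  # absolute value, in [0, 1]
    r2: float


def _compatible_pairs(genotype: np.ndarray):
    """All unordered haplotype pairs compatible with one multi-locus
    genotype (alt-copy counts).  Haplotypes are 0/1 tuples."""
    het = np.flatnonzero(genotype == 1)
    base = np.where(genotype == 2, 1, 0)
    if het.size == 0:
        h = tuple(base.tolist())
        return [(h, h)]
    pairs = []
    # fix the first heterozygous locus to 0 on haplotype one: halves the
    # enumeration, every unordered pair appears exactly once
    for bits in itertools.product((0, 1), repeat=het.size - 1):
        h1 = base.copy()
        h2 = base.copy()
        h1[het[0]], h2[het[0]] = 0, 1
        for locus, bit in zip(het[1:], bits):
            h1[locus], h2[locus] = bit, 1 - bit
        pairs.append((tuple(h1.tolist()), tuple(h2.tolist())))
    return pairs


def em_haplotypes(
    genotypes: np.ndarray,
    loci: tuple[str, ...] | list[str] | None = None,
    variants: list[VariantDef] | None = None,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    n_restarts: int = 5,
    seed: int = 0,
) -> HaplotypeSet:
    """EM haplotype frequency estimation from unphased genotypes.

    ``genotypes`` is an (n_subjects, L) array of alt-copy counts (0/1/2,
    -1 missing); rows with any missing call are excluded.  Iterates until
    max |freq change| < ``tol`` or ``max_iter`` iterations.  The first
    start is uniform over compatible haplotypes; further seeded Dirichlet
    restarts guard against local maxima, and the best log-likelihood wins.
    """
    G = np.asarray(genotypes)
    if G.ndim != 2 or G.shape[1] < 2:
        raise ValueError("genotypes must be (n_subjects, L >= 2)")
    L = G.shape[1]
    if loci is None:
        loci = tuple(
            v.id for v in variants) if variants else tuple(f"locus{j}" for j in range(L))
    loci = tuple(loci)
    G = G[~(G == MISSING).any(axis=1)]
    n = G.shape[0]
    if n == 0:
        raise ValueError("no subject with complete calls over the locus block")

    # index the haplotypes compatible with at least one subject
    hap_index: dict[tuple, int] = {}
    subj_pairs: list[list[tuple[int, int]]] = []
    for row in G:
        pairs = []
        for h1, h2 in _compatible_pairs(row):
            for h in (h1, h2):
                if h not in hap_index:
                    hap_index[h] = len(hap_index)
            pairs.append((hap_index[h1], hap_index[h2]))
        subj_pairs.append(pairs)
    H = len(hap_index)
    haps = [None] * H
    for h, i in hap_index.items():
        haps[i] = h

    if all(len(p) == 1 for p in subj_pairs) or H == 1:
        # phase unambiguous: direct counting is the MLE
        counts = np.zeros(H)
        for pairs in subj_pairs:
            i, j = pairs[0]
            counts[i] += 1
            counts[j] += 1
        freqs = counts / (2 * n)
        ll = _loglik(freqs, subj_pairs)
        return _result(loci, haps, freqs, ll, 0, True, n, variants)

    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(n_restarts, 1)):
        if start == 0:
            f = np.full(H, 1.0 / H)
        else:
            f = rng.dirichlet(np.ones(H))
        f, ll, n_iter, conv = _em_run(f, subj_pairs, H, n, tol, max_iter)
        if best is None or ll > best[1]:
            best = (f, ll, n_iter, conv)
    f, ll, n_iter, conv = best
    return _result(loci, haps, f, ll, n_iter, conv, n, variants)


def _em_run(f, subj_pairs, H, n, tol, max_iter):
    ll = _loglik(f, subj_pairs)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        counts = np.zeros(H)
        for pairs in subj_pairs:
            probs = np.array(
                [(2.0 if i != j else 1.0) * f[i] * f[j] for i, j in pairs]
            )
            tot = probs.sum()
            if tot <= 0:
                # subject incompatible with current freqs: spread uniformly
                probs = np.full(len(pairs), 1.0 / len(pairs))
                tot = 1.0
            probs /= tot
            for (i, j), w in zip(pairs, probs):
                counts[i] += w
                counts[j] += w
        new_f = counts / (2 * n)
        new_ll = _loglik(new_f, subj_pairs)
        if new_ll < ll - 1e-9:
            raise AssertionError(
                f"EM log-likelihood decreased ({ll} -> {new_ll}); "
                "this is a defect"
            )
        delta = np.abs(new_f - f).max()
        f, ll = new_f, new_ll
        if delta < tol:
            converged = True
            break
    return f, ll, it, converged


def _loglik(f, subj_pairs):
    ll = 0.0
    for pairs in subj_pairs:
        p = sum((2.0 if i != j else 1.0) * f[i] * f[j] for i, j in pairs)
        ll += np.log(max(p, 1e-300))
    return float(ll)


def _result(loci, haps, freqs, ll, n_iter, converged, n, variants):
    order = np.argsort([-f for f in freqs], kind="stable")
    labels = []
    for k in order:
        bits = haps[k]
        if variants:
            labels.append(
                "".join(
                    v.allele_alt if b else v.allele_ref
                    for v, b in zip(variants, bits)
                )
            )
        else:
            labels.append("".join(str(b) for b in bits))
    freqs = np.asarray(freqs)[order]
    freqs = freqs / freqs.sum()  # simplex to numerical precision
    return HaplotypeSet(
        loci=tuple(loci),
        haplotypes=tuple(labels),
        freqs=freqs,
        loglik=float(ll),
        n_iter=n_iter,
        converged=converged,
        n_subjects=n,
        bits=tuple(tuple(haps[k]) for k in order),
    )


# ---------------------------------------------------------------------------
# linkage disequilibrium


def ld_from_haplotype_freqs(p_ab: float, p_a: float, p_b: float, pair=("locus0", "locus1")) -> LDStats:
    """LD statistics from two-locus haplotype/allele frequencies.

    ``p_a``/``p_b`` are the frequencies of the chosen allele at each
    locus, ``p_ab`` the frequency of the haplotype carrying both.
    D = p_ab - p_a*p_b; D' = |D| / Dmax with the usual frequency-bound
    Dmax; r2 = D^2 / (p_a(1-p_a)p_b(1-p_b)).
    """
    for name, p in (("p_a", p_a), ("p_b", p_b)):
        if not 0.0 < p < 1.0:
            raise ValueError(f"monomorphic locus: {name} = {p}; LD undefined")
    D = p_ab - p_a * p_b
    if D > 0:
        dmax = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        dmax = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = 0.0 if D == 0 else abs(D) / dmax
    r2 = D * D / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return LDStats(locus_pair=tuple(pair), D=float(D), D_prime=float(d_prime), r2=float(r2))


def pairwise_ld(hapset: HaplotypeSet, locus_pair: tuple[str, str]) -> LDStats:
    """Pairwise D, |D'| and r2 between two loci of an estimated
    haplotype set; the tracked allele is the alternate (or '1') allele."""
    try:
        i = hapset.loci.index(locus_pair[0])
        j = hapset.loci.index(locus_pair[1])
    except ValueError as exc:
        raise ValueError(f"locus not in haplotype set: {exc}") from exc

    # frequencies of the alt allele at each locus and of the alt-alt haplotype
    p_a = p_b = p_ab = 0.0
    for bits, f in zip(hapset.bits, hapset.freqs):
        ai = bool(bits[i])
        bj = bool(bits[j])
        p_a += f * ai
        p_b += f * bj
        p_ab += f * (ai and bj)
    return ld_from_haplotype_freqs(p_ab, p_a, p_b, pair=locus_pair)


# ---------------------------------------------------------------------------
# haplotype-level association


@dataclass
class HaplotypeAssociation:
    haplotype: str
    freq_pooled: float
    freq_cases: float
    freq_controls: float
    or_result: ORResult | None
    em_based: bool = True  # expected counts: uncertainty understated
    pooled_other: bool = False


def haplotype_association(
    case_genotypes: np.ndarray,
    control_genotypes: np.ndarray,
    loci=None,
    variants: list[VariantDef] | None = None,
    min_freq: float = 0.05,
    seed: int = 0,
) -> list[HaplotypeAssociation]:
    """Per-haplotype case-control odds ratios from EM frequencies.

    EM runs separately on cases, controls and pooled; haplotypes with
    pooled frequency above ``min_freq`` are reported individually (each
    against all others) with Woolf CIs on *expected* haplotype counts —
    flagged EM-based because the phase uncertainty is not propagated.
    Rare haplotypes are pooled into an "other" row.  With fewer than two
    common haplotypes, frequencies are reported without ORs.
    """
    case_genotypes = np.asarray(case_genotypes)
    control_genotypes = np.asarray(control_genotypes)
    pooled = np.vstack([case_genotypes, control_genotypes])
    hs_pool = em_haplotypes(pooled, loci, variants, seed=seed)
    hs_case = em_haplotypes(case_genotypes, loci, variants, seed=seed)
    hs_ctrl = em_haplotypes(control_genotypes, loci, variants, seed=seed)
    common = [h for h, f in hs_pool.as_dict().items() if f > min_freq]
    rare = [h for h in hs_pool.haplotypes if h not in common]
    n2_case = 2 * hs_case.n_subjects
    n2_ctrl = 2 * hs_ctrl.n_subjects
    with_ors = len(common) >= 2
    out = []

    def row(haps, pooled_other):
        f_pool = sum(hs_pool.freq(h) for h in haps)
        f_case = sum(hs_case.freq(h) for h in haps)
        f_ctrl = sum(hs_ctrl.freq(h) for h in haps)
        orr = None
        if with_ors:
            a = int(round(f_case * n2_case))
            c = int(round(f_ctrl * n2_ctrl))
            t = TwoByTwo(a=a, b=n2_case - a, c=c, d=n2_ctrl - c)
            label = haps[0] if not pooled_other else "other"
            orr = crude_or(t, contrast_label=f"{label} vs all others")
        return HaplotypeAssociation(
            haplotype=haps[0] if not pooled_other else "other",
            freq_pooled=f_pool,
            freq_cases=f_case,
            freq_controls=f_ctrl,
            or_result=orr,
            pooled_other=pooled_other,
        )

    for h in common:
        out.append(row([h], False))
    if rare:
        out.append(row(rare, True))
    return out
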