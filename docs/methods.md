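# Methods

## Setting

A hospital-based case-control study of hepatocellular carcinoma (611
newly diagnosed cases, 614 cancer-free controls frequency-matched on
age and gender) genotyped three candidate promoter-region variants of
*ARID1B* — rs73013281 C>T, rs167007 A>G, rs9397984 C>T — and recorded
binary lifestyle covariates (smoking, drinking, non-occupational
physical activity, HBsAg serostatus, family history of HCC, gender)
plus age.  ccassoc re-implements that analysis chain as a library; the
individual-level data were never deposited, so the package carries the
published count tables and a synthetic-cohort generator standing in
for the raw data.

## Data model

Genotype calls are stored as copies of the declared alternate allele
(0/1/2, −1 missing).  Every variant declares its odds-ratio baseline
homozygote explicitly: for rs73013281 the baseline CC is the *minor*
homozygote (control T-allele frequency ≈ 0.70), so inferring the
baseline from allele frequency would silently invert the published
contrasts.  Missing handling is complete-case per test: each statistic
drops only subjects missing the fields it uses, which is what makes
the published tables' slightly different denominators (call rates
99.7–99.8%) reproducible.  Genotype strings parse unordered
("CT" ≡ "TC"); unparseable tokens become missing calls, never errors.

## Statistics

**Pearson χ².**  Uncorrected (no Yates continuity correction) on r×c
count tables with expected counts from the margin products; a zero
margin is a hard error.  The uncorrected convention is pinned by the
gender fixture: the published 0.15 is the uncorrected statistic (the
corrected value would be ≈0.10).

**Hardy–Weinberg.**  Asymptotic 1-df goodness-of-fit χ² against
(q̂²N, 2p̂q̂N, p̂²N) with p̂ the alternate-allele frequency; monomorphic
samples return statistic 0 with a flag.  An exact (conditional)
test is available as `hwe_exact_test` but is not the default, since
the original analysis used the goodness-of-fit χ².  Note the published
control counts for rs73013281 give χ² ≈ 4.58 (p ≈ 0.032), in tension
with the study's statement that all variants conformed to HWE; the
package reports what the printed counts imply and does not force
agreement.

**Odds ratios.**  Crude OR = ad/bc with the Woolf log-scale CI and a
two-sided Wald p; z = 1.959964 everywhere.  Any zero cell triggers
Haldane–Anscombe (+0.5 to all four cells) and flags the result; an
all-zero table is an error.  Adjusted ORs are exp(β) from logistic
regression; with an empty adjustment set they reproduce the crude
cross-product exactly (saturated-model identity, tested to 1e-6
relative).

**Logistic fitter.**  Own IRLS implementation with step-halving so the
log-likelihood never decreases; convergence when max|Δβ| < 1e-8 or
|Δloglik| < 1e-10, capped at 100 iterations; vcov is the inverse
observed information.  Separation is detected as any
predictor-standardised |β| > 15 at termination and returned as a
non-converged fit — downstream code must check `converged`, nothing is
silently trusted.  The fitter is cross-checked against an independent
established ML implementation in the test suite.

**Genetic models.**  Codominant (two indicators), dominant, recessive,
additive (0/1/2 non-reference-allele count), all relative to the
declared baseline homozygote.  The study cites an external
model-selection method without describing it; the package ranks the
four converged fits by AIC and reports all of them, so the choice is
auditable rather than hidden.

**Permutation correction.**  Case/control labels are shuffled
uniformly; genotypes and covariates travel with the subject, which
preserves their joint distribution and makes the labels exchangeable
under the global null.  All requested tests share one stream of
shuffles, so the empirical p-values respect the correlation among the
three linked variants.  Empirical p = (r+1)/(B+1) (add-one rule;
default B = 10,000).  The per-test statistic family is fixed across
the stream: for unadjusted tests the classic crude score test for the
coding (2×2/2×3 Pearson χ²; Cochran–Armitage for additive), which
vectorises over all shuffles; for adjusted tests the logistic Wald
test of the genetic term(s), refitted per shuffle, aborting if more
than 1% of refits fail.  Degenerate shuffled tables score p = 1.

**Interaction.**  The genetic factor in interaction analyses is the
collapsed dominant carrier contrast (TT+TC vs CC for rs73013281).
Multiplicative interaction is the two-sided Wald test of the G×E
product term; on a saturated 2×2×2 table the product-term OR equals
the ratio of stratum cross-product ORs (tested to 1e-6).  Additive
interaction uses RERI = OR₁₁ − OR₁₀ − OR₀₁ + 1 from the
joint-exposure coding (indicators G-only, E-only, G-and-E against the
doubly-unexposed cell); AP = RERI/OR₁₁ and S = (OR₁₁−1)/(OR₁₀+OR₀₁−2)
are reported alongside, but RERI drives the p-value.  The bootstrap
resamples subjects with replacement within phenotype groups — the
case-control design fixes those margins — recomputes RERI per
resample, and reports the 2.5/97.5 percentile CI and
p = 2·min(frac ≤ 0, frac > 0) clipped to [2/B, 1]; percentile rather
than BCa intervals for simplicity and determinism.  When no adjustment
covariates are requested the crude joint-exposure ORs are exact
cross-products, so subject resampling reduces to multinomial
resampling of the eight cells — implemented vectorised; the covariate
path refits the logistic model per resample.  The published additive
p-value (0.006) comes from a cited bootstrap construction that the
study does not specify; the RERI-based test here is therefore
validated by its own calibration (type-I error at nominal α under
RERI = 0 simulation) rather than against the printed number.

**Haplotypes.**  Standard EM for unphased diplotypes: the E-step
weights each subject's compatible haplotype pairs by 2fᵢfⱼ (fᵢ² when
homozygous), the M-step re-estimates frequencies from expected counts;
the observed-data log-likelihood is asserted non-decreasing at every
iteration; convergence at max|Δf| < 1e-8, cap 10,000 iterations.  The
first start is uniform over observed-compatible haplotypes with 4
further seeded Dirichlet restarts against local maxima (relevant at
L = 3).  Phase-unambiguous samples reduce to direct counting exactly.
This replaces the original study's external Bayesian phasing program:
only population frequencies, not individual phases, feed the
downstream analysis, and EM is deterministic and testable in-repo.
The test oracle is a coarse grid over the frequency simplex (step
0.05) refined by direct Nelder–Mead maximisation of an independently
coded likelihood; a full 1e-3 grid over the 3-simplex (~10⁸ points)
buys no additional assurance.  |D′| is reported (matching the study's
"D′ > 0.84" convention) with the usual frequency-bound Dmax, and
r² = D²/(p_A p_a p_B p_b).  Haplotype-level ORs use *expected*
haplotype counts from per-group EM fits with Woolf CIs and are flagged
EM-based: phase uncertainty is not propagated, so the CIs are
anti-conservative.  Haplotypes below 5% pooled frequency are collapsed
into "other".

## Synthetic cohorts

The generator draws a prospective population — genotypes Binomial(2, p)
under HWE or diplotypes from configured multi-locus haplotype
frequencies (which induces LD), covariates Bernoulli with optional
pairwise odds-ratio coupling (default independence; the real cohort's
covariate correlation is unknown), age Normal — assigns disease by a
logistic model, and rejection-samples to exactly the target case and
control counts.  Configured odds ratios therefore have a direct
prospective interpretation, and the log-OR estimators are unbiased on
simulated data within Monte-Carlo error (tested).  Interaction on the
multiplicative scale multiplies the joint-cell OR; on the additive
scale the joint-cell log-odds is solved so that
OR₁₁ = OR₁₀ + OR₀₁ − 1 + RERI_target.

Defaults are the study conditions: 611/614 subjects; control
alternate-allele frequencies 0.698/0.919/0.932 (from the published
control genotype counts); covariate prevalences from the control arm
(smoking 0.567, drinking 0.448, inactivity 0.526, HBsAg 0.174, family
history 0.037, male 0.863); age N(55.93, 12.10), carried only as an
adjuster.  Baseline disease risk defaults to 0.05 — a population-scale
lifetime-risk figure plausible for a high-HBV-prevalence region, and
comfortably inside the regime where the case-control OR tracks the
configured conditional OR.  What the generator does *not* emulate:
age/gender frequency-matching (margins are fixed, matching is not
re-implemented), population stratification, genotyping error, and any
real covariate dependence structure beyond the optional pairwise
coupling — so passing calibration tests demonstrates correctness of
the estimators under the stated model, not robustness to those
real-data features.

Power estimation is the fraction of simulated cohorts in which the
Wald p of the configured contrast falls below α, with binomial
Monte-Carlo SE.  The study's printed power values (0.92/0.55/0.50 for
OR 1.50) are not comparison targets: their α, genetic model and
computing method are unstated.

## Reproducibility and problem sizes

Every stochastic routine takes a mandatory seed and is bit-reproducible
given it (permutation streams, bootstrap resamples, simulated cohorts,
report JSON).  The calibration checks in the test suite use 200 null
replicates × 500 shuffles for permutation uniformity (KS at the 1%
level), 500 replicates × 1,000 bootstrap resamples at n = 611/614 for
the additive test's type-I error (±2% of α = 0.05), and 200 replicates
for OR-recovery — sizes at which Monte-Carlo error is small against
the tested tolerances while the whole suite runs in well under a
minute of simulation time.  Production analyses default to the study's
10,000 permutations/resamples.

## Known limitations

- Printed *adjusted* ORs cannot be reproduced to printed precision:
  the joint covariate distribution of the real cohort is not
  recoverable from the published margins.  The adjusted machinery is
  validated by simulation (CI coverage of the generating OR) instead.
- Haplotype ORs understate uncertainty (expected counts, see above).
- The additive-interaction p-value is RERI-based by construction and
  need not coincide with the study's unspecified bootstrap variant.
- No VCF/PLINK input (three candidate SNPs; delimited tables suffice),
  no relatedness handling, no three-way interactions, no case-only
  estimator.
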