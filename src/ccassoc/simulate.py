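"""Synthetic case-control cohorts and simulation-based power.

Population individuals are drawn prospectively — genotypes from
Hardy-Weinberg proportions at configured alternate-allele frequencies
(or diplotypes sampled from configured multi-locus haplotype
frequencies, which induces linkage disequilibrium), binary covariates
Bernoulli, age normal — and disease status from a logistic model with
configured main effects and an optional interaction term.  Rejection
sampling continues until exactly ``n_cases`` cases and ``n_controls``
controls are accumulated, so every configured odds ratio has a direct
prospective interpretation while the fixed case/control margins mirror
the retrospective design.

Defaults emulate the ARID1B hepatocellular-carcinoma study conditions:
611 cases / 614 controls, control-population alternate-allele
frequencies 0.698 / 0.919 / 0.932, lifestyle-covariate prevalences from
the control arm, and age N(55.93, 12.10) used only as an adjuster.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, logit

from .association import GeneticModelCoding, fit_logistic
from .cohort import CohortTable, VariantDef
from .datasets import study_variants

__all__ = [
    "VariantFreq",
    "InteractionSpec",
    "SimulationConfig",
    "PowerEstimate",
    "study_like_config",
    "simulate_cohort",
    "estimate_power",
]


@dataclass(frozen=True)
class VariantFreq:
    """One simulated variant: definition + alternate-allele population
    frequency; ``hwe=True`` draws genotypes as Binomial(2, freq)."""

    variant: VariantDef
    alt_freq: float
    hwe: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alt_freq < 1.0:
            raise ValueError(f"{self.variant.id}: alt_freq must be in (0,1)")


@dataclass(frozen=True)
class InteractionSpec:
    """Configured G x E interaction.

    ``scale="multiplicative"``: ``magnitude`` multiplies the joint-cell
    odds ratio beyond the product of the main effects (1 = no
    interaction).  ``scale="additive"``: ``magnitude`` is the target
    RERI; the joint-cell log-odds is solved so that
    OR11 = OR10 + OR01 - 1 + magnitude (0 = exact additivity).
    """

    variant_id: str
    coding: str
    exposure: str
    scale: str
    magnitude: float

    def __post_init__(self) -> None:
        if self.scale not in ("multiplicative", "additive"):
            raise ValueError("interaction scale must be multiplicative or additive")


@dataclass
class SimulationConfig:
    n_cases: int = 611
    n_controls: int = 614
    variants: list[VariantFreq] = field(default_factory=list)
    haplotype_freqs: dict[str, float] | None = None  # allele strings over variants
    covariate_prevalences: dict[str, float] = field(default_factory=dict)
    covariate_coupling: dict[tuple[str, str], float] = field(default_factory=dict)
    genetic_effects: dict[str, tuple[str, float]] = field(default_factory=dict)
    covariate_effects: dict[str, float] = field(default_factory=dict)
    interaction: InteractionSpec | None = None
    baseline_risk: float = 0.05
    age_mean: float = 55.93
    age_sd: float = 12.10
    seed: int = 0
    draw_cap: int = 2_000_000

    def validate(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("n_cases and n_controls must be positive")
        if not 0.0 < self.baseline_risk < 1.0:
            raise ValueError("baseline_risk must be in (0,1)")
        for name, p in self.covariate_prevalences.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"prevalence of {name!r} must be in (0,1)")
        if self.haplotype_freqs is not None:
            tot = sum(self.haplotype_freqs.values())
            if abs(tot - 1.0) > 1e-9 or min(self.haplotype_freqs.values()) < 0:
                raise ValueError("haplotype_freqs must lie on the simplex")
            L = len(self.variants)
            for h in self.haplotype_freqs:
                if len(h) != L:
                    raise ValueError(f"haplotype {h!r} has wrong length (expect {L})")
        for vid in self.genetic_effects:
            if vid not in {vf.variant.id for vf in self.variants}:
                raise ValueError(f"genetic effect on undeclared variant {vid!r}")
        for name in self.covariate_effects:
            if name != "age" and name not in self.covariate_prevalences:
                raise ValueError(f"effect on undeclared covariate {name!r}")


def study_like_config(seed: int = 0) -> SimulationConfig:
    """Study-condition defaults: sample sizes, allele frequencies and
    covariate prevalences of the hepatocellular-carcinoma cohort."""
    variants = study_variants()
    return SimulationConfig(
        n_cases=611,
        n_controls=614,
        variants=[
            VariantFreq(variants["rs73013281"], 0.698),
            VariantFreq(variants["rs167007"], 0.919),
            VariantFreq(variants["rs9397984"], 0.932),
        ],
        covariate_prevalences={
            "gender": 0.863,
            "smoking": 0.567,
            "drinking": 0.448,
            "physical_activity": 0.526,  # 1 = inactive
            "hbsag": 0.174,
            "family_history": 0.037,
        },
        seed=seed,
    )


@dataclass
class PowerEstimate:
    power: float
    mc_se: float
    n_sims: int
    alpha: float
    detect_or: float
    coding: str
    config: SimulationConfig


# ---------------------------------------------------------------------------


def _joint_bernoulli(rng, n, p1, p2, odds_coupling):
    """Two correlated Bernoulli columns with the given margins and a
    configured pairwise odds ratio: solves the 2x2 joint cell p11."""
    if odds_coupling == 1.0:
        return rng.random(n) < p1, rng.random(n) < p2
    # p11 solves OR = p11*p00 / (p10*p01) with the margins fixed
    a = odds_coupling - 1.0
    b = 1.0 + a * (p1 + p2)
    disc = b * b - 4.0 * a * odds_coupling * p1 * p2
    p11 = (b - np.sqrt(disc)) / (2.0 * a)
    p10 = p1 - p11
    p01 = p2 - p11
    p00 = 1.0 - p11 - p10 - p01
    cells = rng.choice(4, size=n, p=[p00, p10, p01, p11])
    return np.isin(cells, (1, 3)), np.isin(cells, (2, 3))


def _draw_population(cfg: SimulationConfig, rng, n: int):
    """One batch of prospective individuals: genotypes, covariates, age."""
    genotypes = {}
    if cfg.haplotype_freqs:
        haps = list(cfg.haplotype_freqs)
        probs = np.array([cfg.haplotype_freqs[h] for h in haps])
        bits = np.array(
            [
                [0 if ch == vf.variant.allele_ref else 1 for ch, vf in zip(h, cfg.variants)]
                for h in haps
            ],
            dtype=np.int8,
        )
        h1 = rng.choice(len(haps), size=n, p=probs)
        h2 = rng.choice(len(haps), size=n, p=probs)
        calls = bits[h1] + bits[h2]
        for j, vf in enumerate(cfg.variants):
            genotypes[vf.variant.id] = calls[:, j].astype(np.int8)
    else:
        for vf in cfg.variants:
            genotypes[vf.variant.id] = rng.binomial(2, vf.alt_freq, size=n).astype(
                np.int8
            )
    covs: dict[str, np.ndarray] = {}
    coupled = set()
    for (n1, n2), orr in cfg.covariate_coupling.items():
        x1, x2 = _joint_bernoulli(
            rng, n, cfg.covariate_prevalences[n1], cfg.covariate_prevalences[n2], orr
        )
        covs[n1] = x1.astype(float)
        covs[n2] = x2.astype(float)
        coupled |= {n1, n2}
    for name, p in cfg.covariate_prevalences.items():
        if name not in coupled:
            covs[name] = (rng.random(n) < p).astype(float)
    age = rng.normal(cfg.age_mean, cfg.age_sd, size=n)
    return genotypes, covs, age


def _linear_predictor(cfg: SimulationConfig, genotypes, covs, age):
    eta = np.full(next(iter(genotypes.values())).size if genotypes else len(age),
                  logit(cfg.baseline_risk))
    vdefs = {vf.variant.id: vf.variant for vf in cfg.variants}
    gterm = {}
    for vid, (coding_name, log_or) in cfg.genetic_effects.items():
        col = GeneticModelCoding(coding_name).design(genotypes[vid], vdefs[vid])[0][:, 0]
        gterm[vid] = col
        eta = eta + log_or * col
    for name, log_or in cfg.covariate_effects.items():
        x = age if name == "age" else covs[name]
        eta = eta + log_or * x
    if cfg.interaction is not None:
        spec = cfg.interaction
        if spec.variant_id in gterm and cfg.genetic_effects[spec.variant_id][0] == spec.coding:
            gcol = gterm[spec.variant_id]
        else:
            gcol = GeneticModelCoding(spec.coding).design(
                genotypes[spec.variant_id], vdefs[spec.variant_id]
            )[0][:, 0]
        ecol = covs[spec.exposure]
        b_g = cfg.genetic_effects.get(spec.variant_id, (spec.coding, 0.0))[1]
        b_e = cfg.covariate_effects.get(spec.exposure, 0.0)
        if spec.scale == "multiplicative":
            gamma = np.log(spec.magnitude)
        else:
            or11 = np.exp(b_g) + np.exp(b_e) - 1.0 + spec.magnitude
            if or11 <= 0:
                raise ValueError(
                    "additive interaction magnitude makes the joint-cell OR "
                    f"non-positive ({or11:.3f})"
                )
            gamma = np.log(or11) - b_g - b_e
        eta = eta + gamma * gcol * ecol
    return eta


def simulate_cohort(config: SimulationConfig) -> CohortTable:
    """Draw a case-control cohort under the configured disease model.

    Rejection-samples a prospective logistic population until exactly
    ``n_cases`` cases and ``n_controls`` controls are collected;
    bit-reproducible given ``config.seed``.  Raises if the draw cap is hit
    before the quotas fill (baseline risk too small for the budget).
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    need_case, need_ctrl = cfg.n_cases, cfg.n_controls
    acc: dict[str, list] = {"pheno": [], "age": []}
    gen_acc: dict[str, list] = {vf.variant.id: [] for vf in cfg.variants}
    cov_acc: dict[str, list] = {k: [] for k in cfg.covariate_prevalences}
    drawn = 0
    batch = max(2000, int(1.5 * need_case / cfg.baseline_risk / 4))
    while need_case > 0 or need_ctrl > 0:
        if drawn >= cfg.draw_cap:
            raise RuntimeError(
                f"draw cap {cfg.draw_cap} reached with {need_case} cases / "
                f"{need_ctrl} controls still missing; increase baseline_risk "
                "or draw_cap"
            )
        n = min(batch, cfg.draw_cap - drawn)
        drawn += n
        genotypes, covs, age = _draw_population(cfg, rng, n)
        risk = expit(_linear_predictor(cfg, genotypes, covs, age))
        y = (rng.random(n) < risk).astype(np.int8)
        keep_case = np.flatnonzero(y == 1)[:need_case]
        keep_ctrl = np.flatnonzero(y == 0)[:need_ctrl]
        keep = np.sort(np.concatenate([keep_case, keep_ctrl]))
        need_case -= keep_case.size
        need_ctrl -= keep_ctrl.size
        acc["pheno"].append(y[keep])
        acc["age"].append(age[keep])
        for vid in gen_acc:
            gen_acc[vid].append(genotypes[vid][keep])
        for name in cov_acc:
            cov_acc[name].append(covs[name][keep])
    pheno = np.concatenate(acc["pheno"])
    order = np.argsort(pheno == 0, kind="stable")  # cases first, draw order kept
    return CohortTable(
        pheno[order],
        [vf.variant for vf in cfg.variants],
        {vid: np.concatenate(v)[order] for vid, v in gen_acc.items()},
        {k: np.concatenate(v)[order] for k, v in cov_acc.items()},
        np.concatenate(acc["age"])[order],
    )


def estimate_power(
    config: SimulationConfig,
    detect_or: float,
    coding: GeneticModelCoding | str = "dominant",
    alpha: float = 0.05,
    n_sims: int = 200,
    variant_id: str | None = None,
    covariates=(),
) -> PowerEstimate:
    """Monte-Carlo power of the Wald test for a genetic contrast.

    Each simulation replaces the configured effect of ``variant_id``
    (default: the first variant) with log(detect_or) under ``coding``,
    draws a cohort, fits the logistic model and scores p < alpha.
    """
    if isinstance(coding, str):
        coding = GeneticModelCoding(coding)
    if n_sims < 100:
        raise ValueError("n_sims must be at least 100")
    config.validate()
    vid = variant_id or config.variants[0].variant.id
    vdef = next(vf.variant for vf in config.variants if vf.variant.id == vid)
    hits = 0
    from .association import _assemble_design

    for s in range(n_sims):
        cfg = replace(
            config,
            genetic_effects={**config.genetic_effects, vid: (coding.name, float(np.log(detect_or)))},
            seed=int(np.random.default_rng([config.seed, s]).integers(2**31 - 1)),
        )
        cohort = simulate_cohort(cfg)
        y, X, terms, gterms, _ = _assemble_design(cohort, vdef, coding, covariates)
        fit = fit_logistic(y, X, terms=terms)
        if fit.converged and fit.wald_p(gterms[0]) < alpha:
            hits += 1
    p_hat = hits / n_sims
    return PowerEstimate(
        power=p_hat,
        mc_se=float(np.sqrt(p_hat * (1 - p_hat) / n_sims)),
        n_sims=n_sims,
        alpha=alpha,
        detect_or=detect_or,
        coding=coding.name,
        config=config,
    )
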