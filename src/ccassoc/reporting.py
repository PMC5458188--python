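"""End-to-end analysis driver and publication-style table rendering.

:func:`run_full_analysis` chains the stages — covariate comparison,
genotype distribution with chi-square (and optional permutation
p-values), Hardy-Weinberg check, crude/adjusted odds-ratio table,
stratified gene-environment interaction, haplotype frequencies — into a
report bundle of DataFrames, writes them as CSVs plus one deterministic
machine-readable JSON, and renders aligned text tables.

Display rounding follows the usual epidemiology style: 2 decimals for
odds ratios and chi-square statistics, 3 for p-values with "<0.001"
below that.  Significance (two-tailed p < 0.05) is only an annotation;
no row is ever filtered on it.  Raw precision is preserved in the JSON.
A partial-stage failure leaves the bundle usable with the failed stage
recorded; ``ReportBundle.ok`` is True only if everything completed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from . import interaction as inter
from .association import GeneticModelCoding
from .cohort import CohortTable, crosstab_covariate, genotype_counts
from .haplotype import em_haplotypes, pairwise_ld
from .permutation import PermutationTest, permutation_pvalues

logger = logging.getLogger("ccassoc")

__all__ = ["AnalysisConfig", "ReportBundle", "run_full_analysis", "format_or", "format_p"]

ALPHA = 0.05  # two-tailed significance annotation threshold


@dataclass
class AnalysisConfig:
    """What to run and with which settings; seeds are mandatory whenever
    a stochastic stage (permutation, bootstrap) is enabled."""

    variant_ids: list[str] = field(default_factory=list)
    covariate_names: list[str] = field(default_factory=list)
    adjustment_covariates: list[str] = field(default_factory=list)
    codings: list[str] = field(default_factory=lambda: ["codominant", "dominant"])
    interactions: list[tuple[str, str]] = field(default_factory=list)  # (variant, exposure)
    haplotype_loci: list[str] = field(default_factory=list)
    run_permutation: bool = False
    n_perm: int = 10_000
    n_boot: int = 10_000
    seed: int | None = None

    def validate(self, cohort: CohortTable) -> None:
        for v in self.variant_ids + self.haplotype_loci + [v for v, _ in self.interactions]:
            cohort.variant(v)
        for c in self.covariate_names + [e for _, e in self.interactions]:
            cohort.covariate(c)
        for c in self.adjustment_covariates:
            if c == "age":
                if cohort.age is None:
                    raise ValueError("adjustment on age requested but cohort has no age")
            else:
                cohort.covariate(c)
        stochastic = self.run_permutation or self.interactions
        if stochastic and self.seed is None:
            raise ValueError("seed is mandatory when permutation/bootstrap stages run")


@dataclass
class ReportBundle:
    tables: dict[str, pd.DataFrame]
    meta: dict
    failed_stages: dict[str, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failed_stages

    def to_json(self) -> str:
        """Deterministic JSON (sorted keys, full float precision)."""
        payload = {
            "meta": self.meta,
            "failed_stages": self.failed_stages,
            "tables": {
                name: json.loads(df.to_json(orient="split", double_precision=15))
                for name, df in sorted(self.tables.items())
            },
        }
        return json.dumps(payload, sort_keys=True, indent=1)

    def json_digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(outdir / f"{name}.csv", index=False)
        (outdir / "report.json").write_text(self.to_json())

    def render(self) -> str:
        out = []
        for name, df in self.tables.items():
            out.append(f"== {name} ==")
            out.append(df.to_string(index=False))
            out.append("")
        if self.failed_stages:
            out.append("FAILED STAGES: " + ", ".join(self.failed_stages))
        return "\n".join(out)


def format_or(or_point: float, lo: float, hi: float) -> str:
    return f"{or_point:.2f} ({lo:.2f}-{hi:.2f})"


def format_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def _star(p: float) -> str:
    return "*" if p < ALPHA else ""


def run_full_analysis(cohort: CohortTable, config: AnalysisConfig) -> ReportBundle:
    """Run every configured stage on a cohort and bundle the results.

    Stages that raise are recorded in ``failed_stages`` (message kept)
    and the remaining stages still run.
    """
    config.validate(cohort)
    bundle = ReportBundle(
        tables={},
        meta={
            "n_cases": cohort.n_cases,
            "n_controls": cohort.n_controls,
            "seed": config.seed,
            "n_perm": config.n_perm if config.run_permutation else None,
            "n_boot": config.n_boot if config.interactions else None,
            "adjustment": list(config.adjustment_covariates),
        },
    )
    logger.info(
        "run_full_analysis: %s; seed=%s n_perm=%s n_boot=%s",
        cohort,
        config.seed,
        bundle.meta["n_perm"],
        bundle.meta["n_boot"],
    )

    def stage(name, fn):
        try:
            out = fn()
            if out is not None:
                bundle.tables[name] = out
        except Exception as exc:  # noqa: BLE001 - stage isolation is the point
            logger.error("stage %s failed: %s", name, exc)
            bundle.failed_stages[name] = str(exc)

    if config.covariate_names:
        stage("covariates", lambda: _covariate_table(cohort, config))
    if config.variant_ids:
        stage("genotype_distribution", lambda: _genotype_table(cohort, config))
        stage("hwe", lambda: _hwe_table(cohort, config))
        stage("odds_ratios", lambda: _or_table(cohort, config))
    for variant_id, exposure in config.interactions:
        stage(
            f"interaction_{variant_id}_{exposure}",
            lambda v=variant_id, e=exposure: _interaction_table(cohort, config, v, e),
        )
    if len(config.haplotype_loci) >= 2:
        stage("haplotypes", lambda: _haplotype_table(cohort, config))
    return bundle


# ---------------------------------------------------------------------------
# stage implementations


def _covariate_table(cohort, config):
    rows = []
    for name in config.covariate_names:
        t = crosstab_covariate(cohort, name)
        chi = assoc.pearson_chi2(t)
        rows.append(
            {
                "covariate": name,
                "cases_exposed": t.a,
                "cases_unexposed": t.b,
                "controls_exposed": t.c,
                "controls_unexposed": t.d,
                "chi2": round(chi.statistic, 2),
                "p": format_p(chi.p_value) + _star(chi.p_value),
                "p_raw": chi.p_value,
            }
        )
    return pd.DataFrame(rows)


def _genotype_table(cohort, config):
    rows = []
    perm_by_variant = {}
    if config.run_permutation:
        tests = [
            PermutationTest(cohort.variant(v), GeneticModelCoding("codominant"))
            for v in config.variant_ids
        ]
        res = permutation_pvalues(
            cohort, tests, n_perm=config.n_perm, seed=config.seed
        )
        perm_by_variant = {t.variant.id: r for t, r in zip(tests, res)}
    for vid in config.variant_ids:
        var = cohort.variant(vid)
        tab = genotype_counts(cohort, vid)
        chi = assoc.pearson_chi2(tab.counts)
        row = {
            "variant": vid,
            "genotypes": "/".join(var.genotype_label(g) for g in (0, 1, 2)),
            "cases": "/".join(str(c) for c in tab.cases),
            "controls": "/".join(str(c) for c in tab.controls),
            "chi2": round(chi.statistic, 2),
            "p": format_p(chi.p_value) + _star(chi.p_value),
            "p_raw": chi.p_value,
        }
        if vid in perm_by_variant:
            r = perm_by_variant[vid]
            row["p_perm"] = format_p(r.empirical_p)
            row["p_perm_raw"] = r.empirical_p
        rows.append(row)
    return pd.DataFrame(rows)


def _hwe_table(cohort, config):
    rows = []
    for vid in config.variant_ids:
        tab = genotype_counts(cohort, vid)
        res = assoc.hwe_test(tab.controls)
        rows.append(
            {
                "variant": vid,
                "alt_freq_controls": round(res.allele_freq, 3),
                "chi2": round(res.statistic, 2),
                "p": format_p(res.p_value),
                "p_raw": res.p_value,
                "monomorphic": res.monomorphic,
            }
        )
    return pd.DataFrame(rows)


def _or_rows_for(cohort, vid, coding_name, covariates):
    var = cohort.variant(vid)
    coding = GeneticModelCoding(coding_name)
    return assoc.adjusted_or(cohort, var, coding, covariates)


def _or_table(cohort, config):
    rows = []
    for vid in config.variant_ids:
        for coding_name in config.codings:
            crude = _or_rows_for(cohort, vid, coding_name, ())
            adjusted = (
                _or_rows_for(cohort, vid, coding_name, config.adjustment_covariates)
                if config.adjustment_covariates
                else [None] * len(crude)
            )
            for cr, ad in zip(crude, adjusted):
                row = {
                    "variant": vid,
                    "model": coding_name,
                    "contrast": cr.contrast_label,
                    "crude_or_ci": format_or(cr.or_point, cr.ci_low, cr.ci_high),
                    "crude_p": format_p(cr.p_value) + _star(cr.p_value),
                    "crude_or_raw": cr.or_point,
                    "crude_p_raw": cr.p_value,
                }
                if ad is not None:
                    row.update(
                        {
                            "adjusted_or_ci": format_or(ad.or_point, ad.ci_low, ad.ci_high),
                            "adjusted_p": format_p(ad.p_value) + _star(ad.p_value),
                            "adjusted_or_raw": ad.or_point,
                            "adjusted_p_raw": ad.p_value,
                        }
                    )
                rows.append(row)
    return pd.DataFrame(rows)


def _interaction_table(cohort, config, variant_id, exposure):
    var = cohort.variant(variant_id)
    res = inter.pairwise_interaction(
        cohort,
        var,
        exposure,
        covariates=tuple(config.adjustment_covariates),
        n_boot=config.n_boot,
        seed=config.seed,
    )
    rows = []
    for level, orr in res.stratum_ors.items():
        t = orr.counts
        rows.append(
            {
                "stratum": f"{exposure}={level}",
                "cases_carrier/ref": f"{t.a}/{t.b}" if t else "",
                "controls_carrier/ref": f"{t.c}/{t.d}" if t else "",
                "or_ci": format_or(orr.or_point, orr.ci_low, orr.ci_high),
                "p_mult": format_p(res.p_multiplicative) + _star(res.p_multiplicative),
                "p_add": format_p(res.p_additive) + _star(res.p_additive),
                "reri": round(res.reri_point, 3),
                "reri_ci": f"({res.reri_ci[0]:.3f}, {res.reri_ci[1]:.3f})",
                "p_mult_raw": res.p_multiplicative,
                "p_add_raw": res.p_additive,
            }
        )
    return pd.DataFrame(rows)


def _haplotype_table(cohort, config):
    loci = config.haplotype_loci
    variants = [cohort.variant(v) for v in loci]
    G = np.column_stack([cohort.calls(v) for v in loci])
    hs = em_haplotypes(G, loci, variants, seed=config.seed or 0)
    rows = [
        {"haplotype": h, "frequency": round(float(f), 4)}
        for h, f in zip(hs.haplotypes, hs.freqs)
    ]
    df = pd.DataFrame(rows)
    ld_rows = []
    for i in range(len(loci)):
        for j in range(i + 1, len(loci)):
            ld = pairwise_ld(hs, (loci[i], loci[j]))
            ld_rows.append(
                f"{loci[i]}-{loci[j]}: D'={ld.D_prime:.2f} r2={ld.r2:.2f}"
            )
    df.attrs["ld"] = ld_rows
    return df
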