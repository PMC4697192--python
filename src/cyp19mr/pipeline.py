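"""End-to-end regional analysis chain and its run configuration.

The chain mirrors the full procedure: per-study per-allele scans of the
disease outcome -> fixed-effects meta-analysis with the heterogeneity
exclusion -> lead-SNP pick -> conditional scan for secondary signals ->
likelihood-ratio/LD candidate causal set -> BMI-quartile stratification and
gene-environment interaction -> hormone-arm regression -> Wald-ratio
Mendelian-randomization comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import assoc, finemap, meta, mr, strata
from .containers import GenotypeMatrix
from .simulate import SimulationConfig, simulate_disease_through_e2

log = logging.getLogger("cyp19mr")


@dataclass
class RunConfig:
    """Thresholds, covariate choices and external constants for one run.

    Exactly one of (vcf+phenotypes paths) or a simulation config drives a run.
    Defaults: genome-wide threshold 5e-8; secondary/conditional threshold
    1e-4; heterogeneity alpha 0.05; likelihood-ratio bound 100; r2 bound 0.2;
    endometrial per-doubling OR 2.06 (1.47-2.89).
    """

    seed: int = 0
    vcf: str | None = None
    phenotypes: str | None = None
    simulation: SimulationConfig | None = None
    gwas_threshold: float = 5e-8
    conditional_threshold: float = 1e-4
    het_alpha: float = 0.05
    lr_threshold: float = 100.0
    r2_threshold: float = 0.2
    or_doubling: float = mr.OR_DOUBLING_ENDOMETRIAL[0]
    ci_doubling: tuple[float, float] = mr.OR_DOUBLING_ENDOMETRIAL[1]
    disease_covariates: list[str] = field(default_factory=list)
    hormone_covariates: list[str] = field(default_factory=lambda: ["age", "bmi", "hrt", "menopause", "batch", "study"])
    hormone_robust: str = "none"

    def __post_init__(self) -> None:
        for name in ("gwas_threshold", "conditional_threshold", "het_alpha",
                     "lr_threshold", "r2_threshold", "or_doubling"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        has_files = self.vcf is not None or self.phenotypes is not None
        if has_files and self.simulation is not None:
            raise ValueError("give input paths or a simulation config, not both")
        if has_files and (self.vcf is None or self.phenotypes is None):
            raise ValueError("both --vcf and --phenotypes are required for file input")

    @classmethod
    def from_yaml(cls, path: str, seed: int | None = None) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        if seed is not None:
            raw["seed"] = seed
        cfg = cls(**raw)
        if sim is not None:
            sim.setdefault("seed", cfg.seed)
            if "study_sizes" in sim:
                sim["study_sizes"] = tuple(tuple(s) for s in sim["study_sizes"])
            cfg.simulation = SimulationConfig(**sim)
        return cfg


@dataclass
class RegionReport:
    """Everything the chain computes, ready for the summary writer."""

    meta_results: list[meta.MetaResult]
    retained: list[meta.MetaResult]
    excluded: list[meta.MetaResult]
    lead: str
    conditional: list[assoc.AssocResult]
    second_signal: bool
    candidates: finemap.CandidateSet
    bmi_strata: strata.StrataResult | None
    hormone_result: assoc.AssocResult | None
    mr_result: mr.MRResult | None

    def summary_rows(self, genotypes: GenotypeMatrix,
                     phenotypes: pd.DataFrame | None = None) -> list[dict]:
        pos = {v.id: v.position for v in genotypes.variants}
        eff = {v.id: (v.alt_allele if v.effect_allele == "alt" else v.ref_allele)
               for v in genotypes.variants}
        cond_p = {r.variant_id: r.p for r in self.conditional}
        members = {m.variant_id: m for m in self.candidates.members}
        fcase = fctrl = {}
        if phenotypes is not None:
            status = phenotypes.set_index("sample_id")["status"].reindex(genotypes.samples)
            case_mask = (status == 1).to_numpy()
            ctrl_mask = (status == 0).to_numpy()
            vids = genotypes.variant_ids
            fcase = dict(zip(vids, assoc.allele_freq(genotypes, case_mask)))
            fctrl = dict(zip(vids, assoc.allele_freq(genotypes, ctrl_mask)))
        rows = []
        for m in self.meta_results:
            ci = m.ci
            mem = members.get(m.variant_id)
            rows.append({
                "variant_id": m.variant_id,
                "position": pos.get(m.variant_id),
                "effect_allele": eff.get(m.variant_id),
                "freq_case": fcase.get(m.variant_id),
                "freq_ctrl": fctrl.get(m.variant_id),
                "beta": m.beta_pooled, "se": m.se_pooled,
                "or": m.odds_ratio, "ci_lower": ci[0], "ci_upper": ci[1],
                "p": m.p_pooled, "q": m.q_stat, "i2": m.i2, "p_het": m.p_het,
                "excluded_het": m.excluded_het,
                "conditional_p": cond_p.get(m.variant_id),
                "lr_vs_lead": mem.likelihood_ratio if mem else None,
                "r2_with_lead": mem.r2_with_index if mem else None,
                "in_candidate_set": mem is not None,
            })
        return rows


def scan_disease(genotypes: GenotypeMatrix, phenotypes: pd.DataFrame,
                 covariates: list[str], het_alpha: float = 0.05) -> list[meta.MetaResult]:
    """Per-study logistic scans combined by fixed-effects meta-analysis."""
    out = []
    studies = sorted(phenotypes["study"].unique())
    per_study: dict[str, list[assoc.AssocResult]] = {}
    for s in studies:
        sub = phenotypes[phenotypes["study"] == s]
        sub_geno = genotypes.subset_samples(list(sub["sample_id"]))
        res = assoc.logistic_trend(sub_geno, sub, covariates)
        for r in res:
            r.study = s
            per_study.setdefault(r.variant_id, []).append(r)
    for vid in genotypes.variant_ids:
        try:
            out.append(meta.fixed_effects(per_study[vid], het_alpha=het_alpha))
        except ValueError:
            log.info("variant %s: no usable per-study result; dropped", vid)
    return out


def run_region(genotypes: GenotypeMatrix, phenotypes: pd.DataFrame,
               config: RunConfig,
               hormone_genotypes: GenotypeMatrix | None = None,
               hormone_phenotypes: pd.DataFrame | None = None) -> RegionReport:
    """The full chain on one region.

    The hormone arm is optional: without it the report stops after the
    stratified analysis (no MR comparison).
    """
    meta_results = scan_disease(genotypes, phenotypes, config.disease_covariates,
                                config.het_alpha)
    retained, excluded = meta.het_filter(meta_results, config.het_alpha)
    log.info("heterogeneity filter: retained %d, excluded %d", len(retained), len(excluded))
    lead = finemap.pick_lead(retained)
    conditional, second = finemap.conditional_scan(
        genotypes, phenotypes, lead, config.disease_covariates,
        model="logistic", threshold_p=config.conditional_threshold)
    log.info("lead %s; second signal: %s", lead, second)
    candidates = finemap.candidate_set(retained, genotypes, lead,
                                       config.lr_threshold, config.r2_threshold)
    bmi_res = None
    if "bmi" in phenotypes.columns and phenotypes["bmi"].notna().any():
        spec = strata.case_quartiles(phenotypes, "bmi")
        try:
            bmi_res = strata.stratified_assoc(genotypes, phenotypes, spec, lead,
                                              model="logistic", covariates=["age"])
        except ValueError as err:
            log.info("BMI stratification skipped: %s", err)
    hres = mres = None
    if hormone_genotypes is not None and hormone_phenotypes is not None:
        cov = [c for c in config.hormone_covariates if c in hormone_phenotypes.columns]
        target = lead if lead in hormone_genotypes.variant_ids else hormone_genotypes.variant_ids[0]
        hres = assoc.linear_assoc(hormone_genotypes, hormone_phenotypes,
                                  outcome="log_e2", covariates=cov,
                                  robust=config.hormone_robust, variants=[target])[0]
        lead_meta = next(m for m in retained if m.variant_id == lead)
        mres = mr.mr_compare(hres.beta, hres.se, lead_meta.odds_ratio, lead_meta.ci,
                             config.or_doubling, config.ci_doubling)
    return RegionReport(meta_results=meta_results, retained=retained,
                        excluded=excluded, lead=lead, conditional=conditional,
                        second_signal=second, candidates=candidates,
                        bmi_strata=bmi_res, hormone_result=hres, mr_result=mres)


def mr_end_to_end(
    seed: int,
    or_doubling: float = mr.OR_DOUBLING_ENDOMETRIAL[0],
    ci_doubling: tuple[float, float] = mr.OR_DOUBLING_ENDOMETRIAL[1],
    beta_e2: float = 0.096,
    n_cases: int = 6608,
    n_controls: int = 37_925,
    hormone_n: int = 2767,
) -> mr.MRResult:
    """One replicate of the causal-chain consistency check.

    Disease risk is generated *through* estradiol (logistic in ln E2 with the
    per-doubling OR); the observed per-allele OR then comes from the
    case-control arm and the predicted OR from a ``hormone_n``-control
    hormone arm via the Wald ratio. When the generating model is truly
    mediated by E2 the two should be judged compatible.
    """
    cfg = SimulationConfig(seed=seed, n_variants=1)
    geno, pheno = simulate_disease_through_e2(cfg, or_doubling, n_cases, n_controls)
    obs = assoc.logistic_trend(geno, pheno, [])[0]
    controls = pheno[pheno["status"] == 0].head(hormone_n)
    harm_geno = geno.subset_samples(list(controls["sample_id"]))
    hres = assoc.linear_assoc(harm_geno, controls, outcome="log_e2")[0]
    return mr.mr_compare(hres.beta, hres.se, obs.odds_ratio, obs.ci,
                         or_doubling, ci_doubling)
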