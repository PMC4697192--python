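"""Synthetic regional genotype and phenotype generator.

Emulates the statistical structure of a multi-study case-control scan of an
LD-structured SNP region around a hormone-associated locus, plus a
post-menopausal hormone cohort, so the whole association -> meta-analysis ->
fine-mapping -> stratification -> Mendelian-randomization chain can be
exercised without any real data.

Design choices (simplifications, deliberately documented):

* Haplotypes follow a first-order Markov chain along ordered variants with a
  target correlation per adjacent pair -- enough LD realism to exercise r2
  filtering and conditional scans, far cheaper than a coalescent.
* Case-control sampling is retrospective under the rare-disease
  multiplicative model: controls are drawn from the haplotype pool directly;
  case genotype classes at the causal site are reweighted by ``OR**dosage``,
  which is exact for the per-allele logistic target.
* All randomness flows from one explicit integer seed through deterministic
  child streams (``numpy.random.SeedSequence`` spawn keys), so each stage is
  reproducible in isolation and the same seed gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, VariantRecord, check_phenotypes


class ParameterError(ValueError):
    """Raised for infeasible or invalid simulation parameterizations."""


# BMI / age quartile cutpoints of the endometrial-cancer case distribution;
# used as the default generating strata (kg/m2 and years).
BMI_CUTPOINTS = (24.3, 28.0, 33.2)
AGE_CUTPOINTS = (57.0, 63.0, 69.0)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic region and cohorts.

    Defaults reproduce the study's scale: four case-control studies totalling
    6608 cases / 37 925 controls, control effect-allele frequency 0.651 at the
    causal variant with per-allele OR 1.15, and a hormone cohort of n=2767 at
    frequency 0.656 with per-allele effect 0.096 on ln(E2). ``e2_resid_sd``
    defaults to 0.64, which puts the slope standard error near 0.018 at that
    sample size and frequency.
    """

    seed: int
    n_variants: int = 25
    region_start: int = 50_899_000
    region_end: int = 52_095_000
    effect_freqs: np.ndarray | float | None = None  # None: causal_freq everywhere
    causal_index: int = 0
    causal_freq: float = 0.651
    adjacent_r2: float = 0.6
    ld_decay_bp: float | None = None  # None: no distance decay
    log_or: float = float(np.log(1.15))
    # per-study (cases, controls); totals 6608 / 37 925
    study_sizes: tuple[tuple[int, int], ...] = (
        (4402, 28_758),  # iCOGS-scale
        (925, 6225),
        (667, 1288),
        (614, 1654),
    )
    beta_e2: float = 0.096
    beta_t: float = -0.045
    e2_resid_sd: float = 0.64
    t_resid_sd: float = 0.70
    hormone_n: int = 2767
    hormone_freq: float = 0.656
    # covariate effects on ln(E2)
    age_coef: float = 0.004
    bmi_coef: float = 0.03
    hrt_coef: float = -0.10
    menopause_coef: float = 0.05
    batch_sd: float = 0.10
    study_shift: float = 0.08
    cluster_sd: float = 0.0  # family random-effect SD; 0 = independent
    cluster_size: int = 1
    n_batches: int = 6
    interaction_coef: float = 0.0  # added to log-OR per BMI quartile index
    bmi_case: tuple[float, float] = (28.8, 6.5)  # mean, sd
    bmi_ctrl: tuple[float, float] = (25.8, 4.8)
    age_case: tuple[float, float] = (63.0, 8.5)
    age_ctrl: tuple[float, float] = (60.0, 9.5)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ParameterError("seed is mandatory (no implicit global RNG)")
        self.seed = int(self.seed)
        if self.n_variants < 1:
            raise ParameterError("n_variants must be >= 1")
        if not 0.0 < self.causal_freq < 1.0:
            raise ParameterError("causal_freq must lie strictly in (0,1)")
        if not 0.0 <= self.adjacent_r2 <= 1.0:
            raise ParameterError("adjacent_r2 must lie in [0,1]")
        for k, (nca, nco) in enumerate(self.study_sizes):
            if nca <= 0 or nco <= 0:
                raise ParameterError(f"study {k}: case/control counts must be positive")
        if self.e2_resid_sd <= 0 or self.t_resid_sd <= 0:
            raise ParameterError("residual SDs must be positive")
        base = self.causal_freq if self.effect_freqs is None else self.effect_freqs
        freqs = np.broadcast_to(np.asarray(base, float), (self.n_variants,)).copy()
        freqs[self.causal_index] = self.causal_freq
        if np.any((freqs <= 0) | (freqs >= 1)):
            raise ParameterError("effect-allele frequencies must lie in (0,1)")
        self.effect_freqs = freqs

    # deterministic child streams ---------------------------------------------

    def rng(self, *key: int) -> np.random.Generator:
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=tuple(key))
        return np.random.default_rng(ss)

    def positions(self) -> np.ndarray:
        span = self.region_end - self.region_start
        step = max(span // (self.n_variants + 1), 1)
        return self.region_start + step * (1 + np.arange(self.n_variants))

    def variant_records(self) -> list[VariantRecord]:
        pos = self.positions()
        return [
            VariantRecord(
                id=f"snp{j + 1}" if j != self.causal_index else "snp_causal",
                position=int(pos[j]),
                ref_allele="A",
                alt_allele="G",
                effect_allele="alt",
                effect_freq=float(self.effect_freqs[j]),
            )
            for j in range(self.n_variants)
        ]


def _pair_correlation(r2: float, d: float, decay_bp: float | None) -> float:
    rho = float(np.sqrt(r2))
    if decay_bp is not None and decay_bp > 0:
        rho *= float(np.exp(-d / decay_bp))
    return rho


def simulate_haplotypes(config: SimulationConfig, n_haplotypes: int = 20_000) -> np.ndarray:
    """Draw a pool of haplotypes as a first-order Markov chain over variants.

    Marginal allele frequencies follow ``config.effect_freqs``; each adjacent
    pair targets correlation ``sqrt(adjacent_r2)`` (optionally decayed with
    inter-marker distance). Returns an ``n_haplotypes x n_variants`` 0/1 array.

    Raises
    ------
    ParameterError
        If a target frequency/correlation pair is infeasible for binary
        variables (a conditional probability would leave [0, 1]).
    """
    rng = config.rng(0)
    freqs = np.asarray(config.effect_freqs, float)
    pos = config.positions().astype(float)
    m = config.n_variants
    hap = np.empty((n_haplotypes, m), dtype=np.int8)
    hap[:, 0] = rng.random(n_haplotypes) < freqs[0]
    for j in range(1, m):
        p1, p2 = freqs[j - 1], freqs[j]
        q1, q2 = 1 - p1, 1 - p2
        rho = _pair_correlation(config.adjacent_r2, pos[j] - pos[j - 1], config.ld_decay_bp)
        # conditional success probabilities preserving the target marginal
        c1 = p2 + rho * np.sqrt(q1 * p2 * q2 / p1)
        c0 = p2 - rho * np.sqrt(p1 * p2 * q2 / q1)
        if not (0.0 <= c0 <= 1.0 and 0.0 <= c1 <= 1.0):
            raise ParameterError(
                f"adjacent pair {j - 1},{j}: correlation {rho:.3f} infeasible "
                f"for frequencies ({p1:.3f}, {p2:.3f})"
            )
        prev = hap[:, j - 1] == 1
        u = rng.random(n_haplotypes)
        hap[:, j] = np.where(prev, u < c1, u < c0)
    return hap


def case_allele_freq(f_ctrl: float, odds_ratio: float) -> float:
    """Closed-form case effect-allele frequency under the multiplicative model.

    Control genotypes are HWE at frequency ``f_ctrl``; cases reweight genotype
    class g by ``odds_ratio**g``.
    """
    p, q = f_ctrl, 1.0 - f_ctrl
    w = np.array([q * q, 2 * p * q * odds_ratio, p * p * odds_ratio**2])
    w /= w.sum()
    return float((0.5 * w[1] + w[2]))


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int) -> np.ndarray:
    out = rng.normal(mean, sd, size=int(n * 1.6) + 16)
    out = out[(out > lo) & (out < hi)]
    while out.size < n:
        extra = rng.normal(mean, sd, size=n)
        out = np.concatenate([out, extra[(extra > lo) & (extra < hi)]])
    return out[:n]


def _quartile_index(values: np.ndarray, cutpoints: tuple[float, float, float]) -> np.ndarray:
    return np.searchsorted(np.asarray(cutpoints), values, side="right")


def _sample_genotypes_retrospective(
    pool: np.ndarray,
    causal_index: int,
    log_or_per_subject: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw haplotype-pair genotypes with case reweighting at the causal site.

    For each subject with per-allele log-OR ``b`` the causal genotype class g
    is drawn with probability proportional to ``P_HWE(g|pool) * exp(b*g)``,
    then a haplotype is drawn uniformly from the pool stratum carrying the
    required causal allele -- exact for the per-allele target while preserving
    the pool's LD structure. Controls are the special case b=0.
    """
    carriers = np.flatnonzero(pool[:, causal_index] == 1)
    noncarr = np.flatnonzero(pool[:, causal_index] == 0)
    if carriers.size == 0 or noncarr.size == 0:
        raise ParameterError("haplotype pool is monomorphic at the causal site")
    p = carriers.size / pool.shape[0]
    q = 1.0 - p
    n = log_or_per_subject.size
    base = np.array([q * q, 2 * p * q, p * p])
    w = base[None, :] * np.exp(np.outer(log_or_per_subject, np.array([0.0, 1.0, 2.0])))
    w /= w.sum(axis=1, keepdims=True)
    u = rng.random(n)
    g = (u >= w[:, 0]).astype(int) + (u >= w[:, 0] + w[:, 1]).astype(int)
    # draw the two haplotypes per subject from the matching allele strata
    first_is_carrier = np.where(g == 1, rng.random(n) < 0.5, g == 2)
    second_is_carrier = np.where(g == 1, ~first_is_carrier, g == 2)
    def draw(is_carrier: np.ndarray) -> np.ndarray:
        idx = np.empty(n, dtype=int)
        k = is_carrier.sum()
        idx[is_carrier] = rng.choice(carriers, size=k, replace=True)
        idx[~is_carrier] = rng.choice(noncarr, size=n - k, replace=True)
        return idx
    h1 = draw(first_is_carrier)
    h2 = draw(second_is_carrier)
    return pool[h1].astype(float) + pool[h2].astype(float)


def simulate_case_control(
    pool: np.ndarray, config: SimulationConfig
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Retrospectively sample multi-study case-control genotypes + covariates.

    Controls are random haplotype pairs from ``pool``; cases reweight the
    causal genotype class by ``exp(dosage * log_or)``. When
    ``config.interaction_coef`` is nonzero, a subject in BMI quartile k (by
    the case-distribution cutpoints 24.3/28.0/33.2 kg/m2) has per-allele
    log-OR ``log_or + interaction_coef * k``.
    """
    variants = config.variant_records()
    frames = []
    blocks = []
    sample_counter = 0
    for s, (n_cases, n_ctrl) in enumerate(config.study_sizes):
        rng = config.rng(1, s)
        n = n_cases + n_ctrl
        status = np.concatenate([np.ones(n_cases, int), np.zeros(n_ctrl, int)])
        bmi = np.concatenate(
            [
                _truncnorm(rng, *config.bmi_case, 15.0, 60.0, n_cases),
                _truncnorm(rng, *config.bmi_ctrl, 15.0, 60.0, n_ctrl),
            ]
        )
        age = np.concatenate(
            [
                _truncnorm(rng, *config.age_case, 40.0, 90.0, n_cases),
                _truncnorm(rng, *config.age_ctrl, 40.0, 90.0, n_ctrl),
            ]
        )
        log_or = np.zeros(n)
        per_allele = config.log_or
        if config.interaction_coef != 0.0:
            per_allele = config.log_or + config.interaction_coef * _quartile_index(
                bmi, BMI_CUTPOINTS
            )
        log_or[:n_cases] = np.broadcast_to(per_allele, (n,))[:n_cases]
        dosage = _sample_genotypes_retrospective(pool, config.causal_index, log_or, rng)
        ids = [f"s{s + 1}_{sample_counter + i + 1}" for i in range(n)]
        sample_counter += n
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": ids,
                    "status": status,
                    "age": np.round(age, 1),
                    "bmi": np.round(bmi, 1),
                    "hrt": rng.random(n) < 0.3,
                    "menopause": rng.choice(["2-5y", ">5y"], size=n, p=[0.35, 0.65]),
                    "study": f"study{s + 1}",
                    "batch": [f"b{s + 1}_{i % config.n_batches}" for i in range(n)],
                    "cluster_id": [f"c{s + 1}_{i}" for i in range(n)],
                }
            )
        )
        blocks.append(dosage)
    pheno = pd.concat(frames, ignore_index=True)
    pheno["hrt"] = pheno["hrt"].astype(int)
    geno = GenotypeMatrix(
        samples=list(pheno["sample_id"]),
        variants=variants,
        dosage=np.vstack(blocks),
    )
    return geno, check_phenotypes(pheno)


def simulate_hormones(
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    causal_variant: str | None = None,
) -> pd.DataFrame:
    """Simulate post-menopausal ln(E2) and ln(T) for an existing cohort.

    ln(E2) = intercept + beta_e2 * dosage + covariate terms + batch + study
    + optional shared family-cluster effect + Gaussian noise; ln(T) likewise
    with ``beta_t``. Returns a full phenotype table (covariates drawn here).
    """
    rng = config.rng(2)
    n = genotypes.n_samples
    vid = causal_variant or genotypes.variant_ids[config.causal_index]
    dose = genotypes.column(vid)
    age = _truncnorm(rng, 62.0, 7.0, 45.0, 85.0, n)
    bmi = _truncnorm(rng, 26.5, 4.8, 16.0, 55.0, n)
    hrt = (rng.random(n) < 0.25).astype(int)
    meno = rng.choice(["2-5y", ">5y"], size=n, p=[0.3, 0.7])
    study = rng.choice(["EPIC", "SIBS"], size=n, p=[0.7, 0.3])
    batch = rng.integers(0, config.n_batches, size=n)
    batch_eff = rng.normal(0.0, config.batch_sd, size=config.n_batches)
    if config.cluster_size > 1:
        cluster = np.arange(n) // config.cluster_size
    else:
        cluster = np.arange(n)
    cluster_eff = (
        rng.normal(0.0, config.cluster_sd, size=cluster.max() + 1)
        if config.cluster_sd > 0
        else np.zeros(cluster.max() + 1)
    )
    shared = (
        config.age_coef * (age - 62.0)
        + config.bmi_coef * (bmi - 26.5)
        + config.hrt_coef * hrt
        + config.menopause_coef * (meno == ">5y")
        + batch_eff[batch]
        + config.study_shift * (study == "SIBS")
        + cluster_eff[cluster]
    )
    log_e2 = (
        np.log(30.0)
        + config.beta_e2 * dose
        + shared
        + rng.normal(0.0, config.e2_resid_sd, size=n)
    )
    log_t = (
        np.log(0.9)
        + config.beta_t * dose
        + 0.5 * shared
        + rng.normal(0.0, config.t_resid_sd, size=n)
    )
    pheno = pd.DataFrame(
        {
            "sample_id": list(genotypes.samples),
            "status": 0,
            "log_e2": log_e2,
            "log_t": log_t,
            "age": np.round(age, 1),
            "bmi": np.round(bmi, 1),
            "hrt": hrt,
            "menopause": meno,
            "study": study,
            "batch": [f"b{b}" for b in batch],
            "cluster_id": [f"fam{c}" for c in cluster],
        }
    )
    return check_phenotypes(pheno)


def simulate_hormone_cohort(config: SimulationConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """One-variant HWE hormone cohort at ``hormone_freq``, size ``hormone_n``.

    The minimal generator behind the hormone-arm parameter-recovery checks:
    genotypes are Binomial(2, f) and ln(E2)/ln(T) follow the linear model of
    :func:`simulate_hormones`.
    """
    rng = config.rng(3)
    n = config.hormone_n
    dose = rng.binomial(2, config.hormone_freq, size=n).astype(float)
    geno = GenotypeMatrix(
        samples=[f"h{i + 1}" for i in range(n)],
        variants=[
            VariantRecord(
                id="snp_causal",
                position=config.region_start + 1000,
                effect_freq=config.hormone_freq,
            )
        ],
        dosage=dose[:, None],
    )
    pheno = simulate_hormones(geno, config, causal_variant="snp_causal")
    return geno, pheno


def simulate_disease_through_e2(
    config: SimulationConfig,
    or_doubling: float = 2.06,
    n_cases: int = 6608,
    n_controls: int = 37_925,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Generate disease risk *through* estradiol, for the causal-chain check.

    Each subject gets an HWE genotype at ``causal_freq``, then
    ``ln E2 = mu + beta_e2 * dosage + noise``; case status is sampled
    retrospectively with weight ``exp(gamma * ln E2)`` where
    ``gamma = ln(or_doubling) / ln 2`` -- i.e. the disease responds to the
    hormone, not the genotype. E2 is recorded for controls only, mirroring a
    design where hormones are measured in healthy women.

    The induced marginal per-allele log-OR is exactly ``gamma * beta_e2``
    (the Gaussian noise factors out of the retrospective weights), so the
    Wald-ratio prediction from the hormone arm should match the case-control
    estimate up to sampling error.
    """
    if or_doubling <= 0:
        raise ParameterError("or_doubling must be positive")
    rng = config.rng(4)
    gamma = np.log(or_doubling) / np.log(2.0)
    n_pool = 4 * (n_cases + n_controls)
    dose = rng.binomial(2, config.causal_freq, size=n_pool).astype(float)
    log_e2 = np.log(30.0) + config.beta_e2 * dose + rng.normal(0.0, config.e2_resid_sd, n_pool)
    w = np.exp(gamma * (log_e2 - log_e2.mean()))
    case_idx = rng.choice(n_pool, size=n_cases, replace=False, p=w / w.sum())
    rest = np.setdiff1d(np.arange(n_pool), case_idx, assume_unique=False)
    ctrl_idx = rng.choice(rest, size=n_controls, replace=False)
    idx = np.concatenate([case_idx, ctrl_idx])
    status = np.concatenate([np.ones(n_cases, int), np.zeros(n_controls, int)])
    e2 = np.where(status == 1, np.nan, log_e2[idx])  # measured in controls only
    geno = GenotypeMatrix(
        samples=[f"m{i + 1}" for i in range(idx.size)],
        variants=[
            VariantRecord(
                id="snp_causal",
                position=config.region_start + 1000,
                effect_freq=config.causal_freq,
            )
        ],
        dosage=dose[idx][:, None],
    )
    pheno = pd.DataFrame(
        {
            "sample_id": geno.samples,
            "status": status,
            "log_e2": e2,
            "study": "mr_sim",
            "batch": "b0",
            "cluster_id": [f"c{i}" for i in range(idx.size)],
        }
    )
    return geno, check_phenotypes(pheno)


def simulate_quartile_exposure(
    seed: int,
    n_cases: int = 2858,
    n_controls: int = 14_098,
    log_or_per_quartile: float = float(np.log(1.60)),
) -> pd.DataFrame:
    """Retrospective sampling of an ordinal (quartile-index) exposure.

    Controls draw quartile index 0-3 uniformly; cases with probability
    proportional to ``exp(log_or_per_quartile * index)`` -- the retrospective
    counterpart of a logistic model linear in the index. Models an
    anthropometric exposure (e.g. BMI quartile) directly associated with
    case status.
    """
    if n_cases <= 0 or n_controls <= 0:
        raise ParameterError("case/control counts must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(5,)))
    levels = np.arange(4)
    w = np.exp(log_or_per_quartile * levels)
    q_case = rng.choice(levels, size=n_cases, p=w / w.sum())
    q_ctrl = rng.choice(levels, size=n_controls)
    return pd.DataFrame(
        {
            "sample_id": [f"q{i + 1}" for i in range(n_cases + n_controls)],
            "status": np.r_[np.ones(n_cases, int), np.zeros(n_controls, int)],
            "quartile": np.r_[q_case, q_ctrl],
        }
    )
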