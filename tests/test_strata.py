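"""Case-distribution quartiles, stratified estimates and interaction tests."""

import numpy as np
import pandas as pd
import pytest

from cyp19mr import (
    GenotypeMatrix,
    QuartileSpec,
    SimulationConfig,
    VariantRecord,
    case_allele_freq,
    case_quartiles,
    interaction_test,
    simulate_case_control,
    simulate_haplotypes,
    stratified_assoc,
)
from conftest import make_pheno


def hwe_geno(rng, freqs_per_sample):
    dose = rng.binomial(2, freqs_per_sample).astype(float)
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(1, dose.size + 1)],
        variants=[VariantRecord(id="v", position=1)],
        dosage=dose[:, None],
    )


class TestCaseQuartiles:
    def test_uniform_grid_exact_cutpoints(self):
        vals = np.arange(1.0, 101.0)  # 1..100
        pheno = make_pheno(100, status=np.ones(100, int), bmi=vals)
        spec = case_quartiles(pheno, "bmi")
        assert spec.cutpoints == pytest.approx(
            tuple(np.percentile(vals, [25, 50, 75])))

    def test_controls_ignored(self):
        pheno = make_pheno(8, status=[1, 1, 1, 1, 0, 0, 0, 0],
                           bmi=[20, 25, 30, 35, 90, 91, 92, 93])
        spec = case_quartiles(pheno, "bmi")
        assert spec.cutpoints[2] < 40

    def test_too_few_cases_raises(self):
        pheno = make_pheno(3, status=np.ones(3, int), bmi=[20, 25, 30])
        with pytest.raises(ValueError, match=">= 4"):
            case_quartiles(pheno, "bmi")

    @pytest.mark.parametrize(
        "bmi, label",
        [(24.29, "Q1"), (24.3, "Q2"), (28.0, "Q3"), (33.2, "Q4"), (50.0, "Q4")],
    )
    def test_boundary_convention(self, bmi, label):
        # left-closed / right-open with the top interval closed below,
        # matching "<24.3" ... ">=33.2" stratum labels
        spec = QuartileSpec(variable="bmi", cutpoints=(24.3, 28.0, 33.2))
        assert spec.label(bmi) == label

    def test_assignment_partitions_samples(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(28, 6, 1000)
        spec = QuartileSpec(variable="bmi", cutpoints=(24.3, 28.0, 33.2))
        idx = spec.assign(vals)
        assert np.all((idx >= 0) & (idx <= 3))
        assert sum((idx == q).sum() for q in range(4)) == 1000

    def test_nonincreasing_cutpoints_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            QuartileSpec(variable="bmi", cutpoints=(28.0, 24.3, 33.2))


class TestStratifiedAssoc:
    def build(self, seed, per_quartile_or, n_cases=2800, n_ctrl=14_000):
        """One-variant cohort with quartile-specific per-allele ORs."""
        rng = np.random.default_rng(seed)
        spec = QuartileSpec(variable="bmi", cutpoints=(24.3, 28.0, 33.2))
        bmi_case = rng.uniform(16, 45, n_cases)
        bmi_ctrl = rng.uniform(16, 45, n_ctrl)
        f = 0.651
        q_case = spec.assign(bmi_case)
        freqs_case = np.array([case_allele_freq(f, per_quartile_or[q]) for q in q_case])
        geno = hwe_geno(rng, np.r_[freqs_case, np.full(n_ctrl, f)])
        pheno = make_pheno(
            n_cases + n_ctrl,
            status=np.r_[np.ones(n_cases, int), np.zeros(n_ctrl, int)],
            bmi=np.r_[bmi_case, bmi_ctrl],
            age=rng.uniform(45, 80, n_cases + n_ctrl).round(1),
        )
        return geno, pheno, spec

    def test_four_strata_reported(self):
        geno, pheno, spec = self.build(50, [1.15] * 4)
        res = stratified_assoc(geno, pheno, spec, "v", covariates=["age"])
        assert len(res.per_quartile) == 4
        assert [r.study for r in res.per_quartile] == ["Q1", "Q2", "Q3", "Q4"]

    def test_graded_ors_recovered_in_order(self):
        hits = 0
        for seed in range(5):
            geno, pheno, spec = self.build(60 + seed, [1.08, 1.12, 1.21, 1.25])
            res = stratified_assoc(geno, pheno, spec, "v", covariates=["age"])
            ors = [r.odds_ratio for r in res.per_quartile]
            hits += ors[3] > ors[0]
        assert hits >= 4

    def test_empty_stratum_raises_with_name(self):
        geno, pheno, spec = self.build(70, [1.15] * 4, n_cases=400, n_ctrl=2000)
        pheno.loc[spec.assign(pheno["bmi"]) == 3, "bmi"] = 30.0  # empty Q4
        with pytest.raises(ValueError, match="Q4"):
            stratified_assoc(geno, pheno, spec, "v", covariates=["age"])

    def test_small_stratum_rejected_by_floor(self):
        geno, pheno, spec = self.build(71, [1.15] * 4, n_cases=400, n_ctrl=2000)
        mask = spec.assign(pheno["bmi"]) == 3
        drop = pheno.index[mask][30:]
        pheno2 = pheno.drop(drop)
        geno2 = geno.subset_samples(list(pheno2["sample_id"]))
        with pytest.raises(ValueError, match="< 50"):
            stratified_assoc(geno2, pheno2, spec, "v", covariates=["age"])


class TestInteraction:
    def test_null_interaction_type_one_error(self):
        # ~5% rejections at alpha 0.05 when no interaction is generated
        rejections, reps = 0, 120
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            n = 1500
            bmi = rng.uniform(16, 45, n)
            status = rng.integers(0, 2, n)
            f = np.where(status == 1, case_allele_freq(0.5, 1.2), 0.5)
            geno = hwe_geno(rng, f)
            pheno = make_pheno(n, status=status, bmi=bmi)
            spec = QuartileSpec(variable="bmi", cutpoints=(24.3, 28.0, 33.2))
            _, _, p = interaction_test(geno, pheno, spec, "v")
            rejections += p < 0.05
        assert abs(rejections / reps - 0.05) < 0.05

    def test_generated_interaction_detected_positive(self):
        # log-OR increasing by 0.05 per quartile: positive interaction beta
        positives = 0
        for seed in range(10):
            rng = np.random.default_rng(2000 + seed)
            n_cases, n_ctrl = 2858, 14_098
            spec = QuartileSpec(variable="bmi", cutpoints=(24.3, 28.0, 33.2))
            bmi = rng.uniform(16, 45, n_cases + n_ctrl)
            status = np.r_[np.ones(n_cases, int), np.zeros(n_ctrl, int)]
            q = spec.assign(bmi)
            ors = np.exp(np.log(1.10) + 0.05 * q)
            f = np.where(status == 1,
                         [case_allele_freq(0.651, o) for o in ors], 0.651)
            geno = hwe_geno(rng, f)
            pheno = make_pheno(n_cases + n_ctrl, status=status, bmi=bmi)
            beta, _, _ = interaction_test(geno, pheno, spec, "v")
            positives += beta > 0
        assert positives >= 9

    def test_affine_relabeling_leaves_p(self):
        # oracle: refit with quartile index affinely relabeled (2k+5); the
        # product-term Wald P must be unchanged
        import statsmodels.api as sm
        from scipy import stats
        rng = np.random.default_rng(77)
        n = 2000
        spec = QuartileSpec(variable="bmi", cutpoints=(24.3, 28.0, 33.2))
        bmi = rng.uniform(16, 45, n)
        status = rng.integers(0, 2, n)
        f = np.where(status == 1, case_allele_freq(0.5, 1.3), 0.5)
        geno = hwe_geno(rng, f)
        pheno = make_pheno(n, status=status, bmi=bmi)
        _, _, p_pkg = interaction_test(geno, pheno, spec, "v")
        q = 2.0 * spec.assign(bmi) + 5.0
        d = geno.dosage[:, 0]
        X = np.column_stack([np.ones(n), d, q, d * q])
        res = sm.GLM(status, X, family=sm.families.Binomial()).fit()
        p_oracle = float(2 * stats.norm.sf(abs(res.params[3] / res.bse[3])))
        assert p_pkg == pytest.approx(p_oracle, rel=1e-6)

    def test_all_one_quartile_raises(self):
        rng = np.random.default_rng(5)
        n = 200
        geno = hwe_geno(rng, np.full(n, 0.5))
        pheno = make_pheno(n, status=rng.integers(0, 2, n), bmi=np.full(n, 26.0))
        spec = QuartileSpec(variable="bmi", cutpoints=(24.3, 28.0, 33.2))
        with pytest.raises(ValueError, match="single quartile"):
            interaction_test(geno, pheno, spec, "v")

    def test_mostly_missing_quartile_variable_raises(self):
        rng = np.random.default_rng(6)
        n = 200
        geno = hwe_geno(rng, np.full(n, 0.5))
        bmi = np.full(n, np.nan)
        bmi[:20] = rng.uniform(18, 40, 20)
        pheno = make_pheno(n, status=rng.integers(0, 2, n), bmi=bmi)
        spec = QuartileSpec(variable="bmi", cutpoints=(24.3, 28.0, 33.2))
        with pytest.raises(ValueError, match="missing"):
            interaction_test(geno, pheno, spec, "v")

    def test_generator_interaction_flows_through(self):
        # the generator's own genotype-x-BMI interaction produces a positive
        # interaction estimate through the full stratified analysis
        cfg = SimulationConfig(seed=80, n_variants=1, interaction_coef=0.08,
                               study_sizes=((4000, 12_000),))
        pool = simulate_haplotypes(cfg, 10_000)
        geno, pheno = simulate_case_control(pool, cfg)
        spec = case_quartiles(pheno, "bmi")
        beta, _, p = interaction_test(geno, pheno, spec, "snp_causal")
        assert beta > 0


class TestJointVsStratified:
    def test_noiseless_linear_agreement(self):
        # with zero interaction and balanced strata, per-stratum slopes and
        # the joint-model main effect coincide on a noiseless outcome
        rng = np.random.default_rng(90)
        n = 1600
        bmi = np.tile([20.0, 26.0, 30.0, 40.0], n // 4)
        d = rng.integers(0, 3, n).astype(float)
        y = 1.0 + 0.25 * d  # no interaction, no noise
        geno = GenotypeMatrix(
            samples=[f"s{i}" for i in range(1, n + 1)],
            variants=[VariantRecord(id="v", position=1)],
            dosage=d[:, None],
        )
        pheno = make_pheno(n, status=np.ones(n, int), bmi=bmi, log_e2=y)
        spec = QuartileSpec(variable="bmi", cutpoints=(24.3, 28.0, 33.2))
        res = stratified_assoc(geno, pheno, spec, "v", model="linear",
                               outcome="log_e2", min_stratum_n=10)
        for r in res.per_quartile:
            assert r.beta == pytest.approx(0.25, abs=1e-6)
        assert res.interaction_beta == pytest.approx(0.0, abs=1e-6)
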