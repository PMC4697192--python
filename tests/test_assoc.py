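"""Association engines vs independent oracles (grid-search MLE, hand sandwich)."""

import numpy as np
import pandas as pd
import pytest

from cyp19mr import (
    GenotypeMatrix,
    VariantRecord,
    allele_freq,
    case_case_test,
    linear_assoc,
    logistic_trend,
)
from conftest import make_pheno


def table_to_data(cases, controls):
    """Expand genotype-class counts (cases, controls indexed by g=0,1,2)."""
    dose, status = [], []
    for g in range(3):
        dose += [g] * cases[g] + [g] * controls[g]
        status += [1] * cases[g] + [0] * controls[g]
    dose = np.array(dose, float)
    geno = GenotypeMatrix(
        samples=[f"s{i}" for i in range(1, dose.size + 1)],
        variants=[VariantRecord(id="v", position=1)],
        dosage=dose[:, None],
    )
    pheno = make_pheno(dose.size, status=np.array(status))
    return geno, pheno


def grid_mle(cases, controls, lo=-6.0, hi=6.0, rounds=8, width=41):
    """Independent oracle: direct likelihood maximization over an
    (intercept, beta) grid with successive refinement."""
    g = np.array([0.0, 1.0, 2.0])
    n1 = np.array(cases, float)
    n0 = np.array(controls, float)
    a_lo, a_hi, b_lo, b_hi = lo, hi, lo, hi
    best = (0.0, 0.0)
    for _ in range(rounds):
        a = np.linspace(a_lo, a_hi, width)
        b = np.linspace(b_lo, b_hi, width)
        A, B = np.meshgrid(a, b, indexing="ij")
        eta = A[..., None] + B[..., None] * g  # (wa, wb, 3)
        ll = np.sum(n1 * eta - (n1 + n0) * np.logaddexp(0.0, eta), axis=-1)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        best = (a[i], b[j])
        da, db = (a_hi - a_lo) / (width - 1), (b_hi - b_lo) / (width - 1)
        a_lo, a_hi = best[0] - 2 * da, best[0] + 2 * da
        b_lo, b_hi = best[1] - 2 * db, best[1] + 2 * db
    return best


class TestLogisticTrend:
    def test_null_symmetry_or_one(self):
        geno, pheno = table_to_data((20, 20, 10), (20, 20, 10))
        res = logistic_trend(geno, pheno)[0]
        assert res.odds_ratio == pytest.approx(1.0, abs=1e-6)

    def test_matches_grid_search_oracle(self):
        geno, pheno = table_to_data((10, 20, 10), (20, 20, 10))
        res = logistic_trend(geno, pheno)[0]
        _, beta_star = grid_mle((10, 20, 10), (20, 20, 10))
        assert res.beta == pytest.approx(beta_star, abs=1e-6)

    def test_oracle_agreement_on_random_tables(self):
        # property: MLE equals the grid-search oracle on random 2x3 tables
        rng = np.random.default_rng(42)
        for _ in range(100):
            cases = tuple(rng.integers(2, 60, 3))
            controls = tuple(rng.integers(2, 60, 3))
            geno, pheno = table_to_data(cases, controls)
            res = logistic_trend(geno, pheno)[0]
            _, beta_star = grid_mle(cases, controls)
            assert res.beta == pytest.approx(beta_star, abs=1e-5)

    def test_case_control_frequencies_reported(self):
        geno, pheno = table_to_data((0, 10, 10), (10, 10, 0))
        res = logistic_trend(geno, pheno)[0]
        assert res.freq_case == pytest.approx(0.75)
        assert res.freq_ctrl == pytest.approx(0.25)

    def test_single_class_outcome_raises(self):
        geno, pheno = table_to_data((10, 20, 10), (0, 0, 0))
        with pytest.raises(ValueError, match="single class"):
            logistic_trend(geno, pheno)

    def test_separation_flagged_not_raised(self):
        # all carriers are cases -> quasi-separation; result flagged, no crash
        geno, pheno = table_to_data((0, 30, 30), (60, 0, 0))
        res = logistic_trend(geno, pheno)[0]
        assert not res.converged
        assert np.isnan(res.beta)

    def test_orthogonal_covariate_leaves_beta(self):
        geno, pheno = table_to_data((10, 20, 10), (20, 20, 10))
        base = logistic_trend(geno, pheno)[0]
        dose = geno.dosage[:, 0]
        cov = np.ones_like(dose)
        # balanced +-1 within each genotype-by-status cell -> orthogonal
        for g in range(3):
            for s in (0, 1):
                idx = np.flatnonzero((dose == g) & (pheno.status == s))
                half = len(idx) // 2
                cov[idx[:half]] = -1.0
        pheno2 = pheno.assign(z=cov)
        adj = logistic_trend(geno, pheno2, ["z"])[0]
        assert adj.beta == pytest.approx(base.beta, abs=1e-6)

    def test_effect_allele_swap_negates_beta(self):
        geno, pheno = table_to_data((10, 20, 30), (30, 20, 10))
        res = logistic_trend(geno, pheno)[0]
        flipped = GenotypeMatrix(
            samples=geno.samples, variants=geno.variants, dosage=2.0 - geno.dosage
        )
        res_f = logistic_trend(flipped, pheno)[0]
        assert res_f.beta == pytest.approx(-res.beta, abs=1e-7)
        assert res_f.freq_case == pytest.approx(1 - res.freq_case)


class TestLinearAssoc:
    def test_noiseless_fit_exact(self, toy_genotypes):
        dose = toy_genotypes.dosage[:, 0]
        pheno = make_pheno(6, status=np.zeros(6, int), log_e2=1.5 + 0.7 * dose)
        res = linear_assoc(toy_genotypes, pheno, variants=["v1"])[0]
        assert res.beta == pytest.approx(0.7, abs=1e-10)
        assert res.p < 1e-12

    def test_cluster_sandwich_matches_matrix_oracle(self, toy_genotypes):
        rng = np.random.default_rng(7)
        y = 0.4 * toy_genotypes.dosage[:, 0] + rng.normal(size=6)
        clusters = ["c1", "c1", "c2", "c2", "c3", "c3"]
        pheno = make_pheno(6, status=np.zeros(6, int), log_e2=y, cluster_id=clusters)
        res = linear_assoc(toy_genotypes, pheno, robust="cluster", variants=["v1"])[0]
        # explicit (X'X)^-1 (sum_g X_g' e e' X_g) (X'X)^-1 with the
        # G/(G-1)*(n-1)/(n-k) small-sample factor
        X = np.column_stack([np.ones(6), toy_genotypes.dosage[:, 0]])
        bhat = np.linalg.solve(X.T @ X, X.T @ y)
        e = y - X @ bhat
        meat = np.zeros((2, 2))
        for c in ("c1", "c2", "c3"):
            m = np.array(clusters) == c
            s = X[m].T @ e[m]
            meat += np.outer(s, s)
        bread = np.linalg.inv(X.T @ X)
        factor = (3 / 2) * (5 / 4)
        V = factor * bread @ meat @ bread
        assert res.se == pytest.approx(np.sqrt(V[1, 1]), abs=1e-10)

    def test_singleton_clusters_equal_hc1(self, toy_genotypes):
        rng = np.random.default_rng(8)
        y = 0.2 * toy_genotypes.dosage[:, 0] + rng.normal(size=6)
        pheno = make_pheno(6, status=np.zeros(6, int), log_e2=y,
                           cluster_id=[f"c{i}" for i in range(6)])
        res = linear_assoc(toy_genotypes, pheno, robust="cluster", variants=["v1"])[0]
        import statsmodels.api as sm
        X = np.column_stack([np.ones(6), toy_genotypes.dosage[:, 0]])
        hc1 = sm.OLS(y, X).fit(cov_type="HC1").bse[1]
        assert res.se == pytest.approx(hc1, rel=1e-9)

    def test_constant_outcome_raises(self, toy_genotypes):
        pheno = make_pheno(6, status=np.zeros(6, int), log_e2=np.ones(6))
        with pytest.raises(ValueError, match="constant"):
            linear_assoc(toy_genotypes, pheno, variants=["v1"])

    def test_single_cluster_rejected(self, toy_genotypes):
        rng = np.random.default_rng(9)
        pheno = make_pheno(6, status=np.zeros(6, int),
                           log_e2=rng.normal(size=6), cluster_id=["c1"] * 6)
        with pytest.raises(ValueError, match="clusters"):
            linear_assoc(toy_genotypes, pheno, robust="cluster", variants=["v1"])


class TestAlleleFreq:
    @pytest.mark.parametrize(
        "dosages, expected",
        [([0, 1, 2], 0.5), ([2, 2, 1, 1], 0.75), ([2, np.nan, 0], 0.5)],
    )
    def test_frequency(self, dosages, expected):
        d = np.asarray(dosages, float)
        geno = GenotypeMatrix(
            samples=[f"s{i}" for i in range(d.size)],
            variants=[VariantRecord(id="v", position=1)],
            dosage=np.nan_to_num(d)[:, None],
            missing_mask=np.isnan(d)[:, None],
        )
        assert allele_freq(geno)[0] == pytest.approx(expected)

    def test_all_missing_is_nan_with_warning(self):
        geno = GenotypeMatrix(
            samples=["a", "b"],
            variants=[VariantRecord(id="v", position=1)],
            dosage=np.zeros((2, 1)),
            missing_mask=np.ones((2, 1), bool),
        )
        with pytest.warns(UserWarning, match="all-missing"):
            f = allele_freq(geno)
        assert np.isnan(f[0])


class TestCaseCase:
    def test_identical_subgroups_or_one(self):
        # both histology halves carry the exact same genotype counts
        geno, pheno = table_to_data((40, 40, 20), (40, 40, 20))
        pheno["histology"] = np.where(pheno["status"] == 1, "endometrioid", "other")
        pheno["status"] = 1  # everyone a case
        res = case_case_test(geno, pheno, "histology")[0]
        assert res.odds_ratio == pytest.approx(1.0, abs=1e-6)

    def test_empty_subgroup_raises(self):
        geno, pheno = table_to_data((10, 20, 10), (10, 10, 10))
        pheno["histology"] = "endometrioid"
        with pytest.raises(ValueError, match="distinct"):
            case_case_test(geno, pheno, "histology")

    def test_differential_subgroup_ors(self):
        # subgroups simulated with ORs 1.6 / 1.0 vs controls -> the case-case
        # OR centers on the closed-form ratio of per-allele odds
        from cyp19mr import case_allele_freq
        rng = np.random.default_rng(21)
        n = 4000
        f_a = case_allele_freq(0.5, 1.6)
        g_a = rng.binomial(2, f_a, n)
        g_b = rng.binomial(2, 0.5, n)
        dose = np.concatenate([g_a, g_b]).astype(float)
        geno = GenotypeMatrix(
            samples=[f"s{i}" for i in range(1, 2 * n + 1)],
            variants=[VariantRecord(id="v", position=1)],
            dosage=dose[:, None],
        )
        pheno = make_pheno(2 * n, status=np.ones(2 * n, int),
                           histology=["a"] * n + ["b"] * n)
        res = case_case_test(geno, pheno, "histology")[0]
        assert np.isfinite(res.beta)
        assert abs(abs(res.beta) - abs(np.log(1.6))) < 0.15
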