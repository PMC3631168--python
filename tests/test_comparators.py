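"""Benchmark tests: logistic engine, min-p scan, PCA, CCU, covariance."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import optimize

from coassoc import GenotypeDataset
from coassoc._kernels import STAT_CC1, stratum_stat
from coassoc.comparators import (
    ccu_test,
    covariance_test,
    fit_logistic,
    pca_logistic_test,
    snp_logistic_minp,
)
from coassoc.statistic import ResamplingPlan

from conftest import make_dataset


class TestLogisticEngine:
    def test_intercept_only_closed_form(self):
        y = np.array([1.0] * 30 + [0.0] * 70)
        fit = fit_logistic(np.ones((100, 1)), y)
        assert fit.converged
        assert fit.coefficients[0] == pytest.approx(np.log(30 / 70), abs=1e-8)

    def test_two_by_two_log_odds_ratio(self):
        # exposed: 20 cases / 30 controls; unexposed: 10 cases / 40 controls
        x = np.concatenate([np.ones(50), np.zeros(50)])
        y = np.concatenate([np.ones(20), np.zeros(30), np.ones(10), np.zeros(40)])
        X = np.column_stack([np.ones(100), x])
        fit = fit_logistic(X, y)
        assert fit.coefficients[1] == pytest.approx(np.log((20 * 40) / (30 * 10)), abs=1e-8)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        X = np.column_stack([np.ones(200), rng.standard_normal((200, 2))])
        eta = X @ np.array([-0.5, 0.8, -0.3])
        y = (rng.random(200) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = fit_logistic(X, y)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.standard_errors, ref.bse, atol=1e-5)

    def test_separation_flagged(self):
        x = np.concatenate([np.ones(20), np.zeros(20)])
        y = x.copy()
        fit = fit_logistic(np.column_stack([np.ones(40), x]), y)
        assert not fit.converged

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.standard_normal(60)
        X = np.column_stack([np.ones(60), x, 2 * x])
        y = (rng.random(60) < 0.5).astype(float)
        with pytest.raises(ValueError, match="collinear"):
            fit_logistic(X, y)


class TestSnpLogisticMinp:
    def test_single_pair_reduces_to_plain_interaction_test(self, rng):
        ds = make_dataset(rng, n_case=80, n_ctrl=80, p=1, q=1)
        res = snp_logistic_minp(ds, "GA", "GB", n_perm=400, seed=3)
        assert len(res.detail) == 1
        # with one pair there is no selection effect: the adjusted p is the
        # pair's own permutation p, consistent with the asymptotic Wald p
        assert abs(res.p_value - res.detail["p_unadj"].iloc[0]) < 0.25

    def test_duplicated_snp_columns_share_p(self, rng):
        base = make_dataset(rng, n_case=70, n_ctrl=70, p=2, q=2)
        dos = np.column_stack([base.dosages, base.dosages[:, 0]])
        ds = GenotypeDataset(
            dos,
            base.snp_ids + ["a_dup"],
            {**base.gene_of_snp, "a_dup": "GA"},
            base.phenotype,
            base.sample_ids,
        )
        res = snp_logistic_minp(ds, "GA", "GB", n_perm=50, seed=1)
        d = res.detail.set_index(["snp_a", "snp_b"])
        for b in ("b0", "b1"):
            assert d.loc[("a0", b), "p_unadj"] == pytest.approx(
                d.loc[("a_dup", b), "p_unadj"], abs=1e-10
            )


class TestPcaLogistic:
    def test_one_snp_per_gene_equals_pairwise_wald(self, rng):
        """PC1 of a single SNP is an affine map of the dosage, and the Wald z
        of a product term is invariant to affine predictor maps."""
        ds = make_dataset(rng, n_case=90, n_ctrl=90, p=1, q=1)
        pca = pca_logistic_test(ds, "GA", "GB")
        g1 = ds.dosages[:, 0]
        g2 = ds.dosages[:, 1]
        X = np.column_stack([np.ones_like(g1), g1, g2, g1 * g2])
        direct = fit_logistic(X, ds.phenotype.astype(float))
        assert pca.p_value == pytest.approx(direct.p_values[3], abs=1e-6)

    def test_detail_has_interaction_term(self, small_dataset):
        res = pca_logistic_test(small_dataset, "GA", "GB")
        assert "pc1_a:pc1_b" in set(res.detail["term"])
        assert 0 < res.p_value <= 1


class TestCcu:
    def test_one_snp_per_gene_cc1_is_absolute_pearson(self, rng):
        ds = make_dataset(rng, n_case=60, n_ctrl=60, p=1, q=1)
        res = ccu_test(ds, "GA", "GB", ResamplingPlan(19, 30, seed=1))
        case = ds.phenotype == 1
        r_case = np.corrcoef(ds.dosages[case, 0], ds.dosages[case, 1])[0, 1]
        assert res.detail["cc1_case"].iloc[0] == pytest.approx(abs(r_case), abs=1e-10)

    def test_cc1_matches_brute_force_maximization(self):
        """First canonical correlation equals the direct maximum of
        cor(X a, Y b) over unit coefficient vectors (optimizer oracle)."""
        rng = np.random.default_rng(42)
        Z = rng.standard_normal((300, 9)) @ (np.eye(9) + 0.4 * rng.standard_normal((9, 9)) / 3)
        p = 5
        cc1, _, ok = stratum_stat(np.ascontiguousarray(Z), p, STAT_CC1, 1e-6, 300)
        assert ok
        X = Z[:, :p] - Z[:, :p].mean(axis=0)
        Y = Z[:, p:] - Z[:, p:].mean(axis=0)

        def neg_corr(ab):
            a, b = ab[:p], ab[p:]
            sx, sy = X @ a, Y @ b
            return -abs(np.corrcoef(sx, sy)[0, 1])

        best = 0.0
        for s in range(6):
            x0 = np.random.default_rng(s).standard_normal(9)
            r = optimize.minimize(neg_corr, x0, method="Nelder-Mead",
                                  options={"maxiter": 5000, "xatol": 1e-8, "fatol": 1e-12})
            best = max(best, -r.fun)
        assert cc1 == pytest.approx(best, abs=1e-3)

    def test_identical_strata_give_zero_statistic(self, rng):
        base = make_dataset(rng, n_case=50, n_ctrl=0)
        dos = np.vstack([base.dosages, base.dosages])
        pheno = np.concatenate([np.ones(50, dtype=np.int8), np.zeros(50, dtype=np.int8)])
        ds = GenotypeDataset(dos, base.snp_ids, base.gene_of_snp, pheno,
                             [f"s{i}" for i in range(100)])
        res = ccu_test(ds, "GA", "GB", ResamplingPlan(19, 30, seed=2))
        assert res.statistic == pytest.approx(0.0, abs=1e-10)

    def test_small_stratum_rejected(self, rng):
        ds = make_dataset(rng, n_case=6, n_ctrl=60, p=3, q=4)
        with pytest.raises(ValueError, match="exceed"):
            ccu_test(ds, "GA", "GB", ResamplingPlan(19, 30, seed=2))


class TestCovariance:
    def test_identical_strata_give_zero(self, rng):
        base = make_dataset(rng, n_case=50, n_ctrl=0)
        dos = np.vstack([base.dosages, base.dosages])
        pheno = np.concatenate([np.ones(50, dtype=np.int8), np.zeros(50, dtype=np.int8)])
        ds = GenotypeDataset(dos, base.snp_ids, base.gene_of_snp, pheno,
                             [f"s{i}" for i in range(100)])
        res = covariance_test(ds, "GA", "GB", n_perm=99, seed=1, n_boot=60)
        assert res.statistic == pytest.approx(0.0, abs=1e-16)
        assert res.p_value == 1.0

    def test_rank_deficient_blocks_never_fail(self, rng):
        """Duplicated SNP columns (perfect collinearity) are exactly the case
        where the inverse-based form breaks; the pseudo-inverse path must
        still return a finite statistic and a valid p."""
        base = make_dataset(rng, n_case=60, n_ctrl=60, p=2, q=2)
        dos = np.column_stack([base.dosages, base.dosages[:, 0]])
        ds = GenotypeDataset(dos, base.snp_ids + ["a_dup"],
                             {**base.gene_of_snp, "a_dup": "GA"},
                             base.phenotype, base.sample_ids)
        res = covariance_test(ds, "GA", "GB", n_perm=99, seed=2, n_boot=60)
        assert np.isfinite(res.statistic)
        assert 0 < res.p_value <= 1

    def test_full_joint_scope_runs(self, small_dataset):
        res = covariance_test(small_dataset, "GA", "GB", n_perm=49, seed=3, n_boot=50,
                              scope="full_joint")
        assert np.isfinite(res.statistic)
        assert res.detail["scope"].iloc[0] == "full_joint"
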