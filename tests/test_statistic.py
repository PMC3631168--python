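"""Co-association statistic U: formula, resampling behavior, invariances."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from coassoc import GenotypeDataset, ResamplingPlan, bootstrap_path_variance, coassociation_test
from coassoc.plspm import PlspmConfig

from conftest import make_dataset


def swap_labels(ds: GenotypeDataset) -> GenotypeDataset:
    return GenotypeDataset(
        ds.dosages, ds.snp_ids, ds.gene_of_snp, 1 - ds.phenotype, ds.sample_ids
    )


class TestStatisticDefinition:
    def test_u_matches_its_components(self, small_dataset):
        res = coassociation_test(small_dataset, "GA", "GB", ResamplingPlan(99, 50, seed=1))
        expected = (res.beta_case - res.beta_control) / np.sqrt(res.var_case + res.var_control)
        assert res.U == pytest.approx(expected, abs=1e-12)
        assert 0 < res.p_perm <= 1

    def test_exact_null_identical_strata(self, rng):
        """Case and control strata built as copies of the same rows: U = 0 and
        the permutation p-value is large (every permuted |U*| >= 0)."""
        base = make_dataset(rng, n_case=40, n_ctrl=0)
        dos = np.vstack([base.dosages, base.dosages])
        pheno = np.concatenate([np.ones(40, dtype=np.int8), np.zeros(40, dtype=np.int8)])
        ds = GenotypeDataset(
            dos, base.snp_ids, base.gene_of_snp, pheno, [f"s{i}" for i in range(80)]
        )
        res = coassociation_test(ds, "GA", "GB", ResamplingPlan(199, 50, seed=3))
        assert res.beta_case == pytest.approx(res.beta_control, abs=1e-12)
        assert res.U == pytest.approx(0.0, abs=1e-10)
        assert res.p_perm >= 0.3

    def test_p_never_zero(self, small_dataset):
        res = coassociation_test(small_dataset, "GA", "GB", ResamplingPlan(49, 50, seed=2))
        assert res.p_perm >= 1 / (1 + 49)

    def test_label_swap_negates_u_and_keeps_p(self, small_dataset):
        plan = ResamplingPlan(199, 100, seed=7)
        res = coassociation_test(small_dataset, "GA", "GB", plan)
        res_sw = coassociation_test(swap_labels(small_dataset), "GA", "GB", plan)
        assert res_sw.U == pytest.approx(-res.U, abs=0)
        assert res_sw.p_perm == res.p_perm

    def test_deterministic_given_seed(self, small_dataset):
        plan = ResamplingPlan(99, 50, seed=11)
        r1 = coassociation_test(small_dataset, "GA", "GB", plan)
        r2 = coassociation_test(small_dataset, "GA", "GB", plan)
        for f in ("beta_case", "beta_control", "var_case", "var_control", "U", "p_perm"):
            assert getattr(r1, f) == getattr(r2, f)

    def test_unknown_gene_and_small_stratum_errors(self, small_dataset):
        with pytest.raises(ValueError, match="gene"):
            coassociation_test(small_dataset, "GA", "NOPE")
        tiny = make_dataset(np.random.default_rng(0), n_case=5, n_ctrl=40)
        with pytest.raises(ValueError, match="stratum"):
            coassociation_test(tiny, "GA", "GB")


class TestBootstrap:
    def test_degenerate_perfect_correlation_has_zero_variance(self, rng):
        x = rng.standard_normal((40, 1))
        var, table, fails = bootstrap_path_variance(x, x.copy(), n_boot=50, seed=5)
        assert var == pytest.approx(0.0, abs=1e-20)
        assert fails == 0
        assert len(table) == 2

    @staticmethod
    def _mc_variance(gen, n_rep=1000):
        from coassoc._kernels import STAT_PLSPM, stratum_stat

        betas = np.empty(n_rep)
        for i in range(n_rep):
            Xi, Yi = gen(10_000 + i)
            betas[i], _, _ = stratum_stat(
                np.ascontiguousarray(np.hstack([Xi, Yi])), Xi.shape[1], STAT_PLSPM, 1e-6, 300
            )
        return betas.var(ddof=1)

    def test_variance_tracks_monte_carlo_truth_when_identified(self):
        """On a design with a real shared factor (well-identified leading
        direction) the bootstrap variance of the path coefficient is within a
        factor 1.5 of the Monte-Carlo variance over fresh datasets from the
        same generator (independent re-simulation oracle)."""

        def gen(seed, rho=0.5):
            r = np.random.default_rng(seed)
            f = r.standard_normal((300, 1))
            X = np.sqrt(rho) * f + np.sqrt(1 - rho) * r.standard_normal((300, 6))
            Y = np.sqrt(rho) * f + np.sqrt(1 - rho) * r.standard_normal((300, 4))
            return X, Y

        X, Y = gen(123)
        var_boot, _, _ = bootstrap_path_variance(X, Y, n_boot=1000, seed=9)
        var_mc = self._mc_variance(gen)
        assert var_boot == pytest.approx(var_mc, rel=0.5)

    def test_variance_conservative_under_null(self):
        """With independent blocks the latent direction is unidentified and
        the bootstrap variance is inflated (never anti-conservative): it
        stays above the Monte-Carlo truth but within a factor ~2.5.  The
        permutation p-value is unaffected because the denominator is held
        fixed across permutations."""

        def gen(seed):
            r = np.random.default_rng(seed)
            return r.standard_normal((300, 6)), r.standard_normal((300, 4))

        X, Y = gen(123)
        var_boot, _, _ = bootstrap_path_variance(X, Y, n_boot=1000, seed=9)
        var_mc = self._mc_variance(gen)
        assert var_mc <= var_boot <= 2.5 * var_mc

    def test_small_stratum_rejected(self, rng):
        x = rng.standard_normal((6, 2))
        with pytest.raises(ValueError, match="at least 10"):
            bootstrap_path_variance(x, x + 0.1, n_boot=20, seed=0)


class TestPermutationModes:
    def test_full_recompute_agrees_with_numerator_only_null(self, rng):
        """Both permutation modes give compatible p-values on null data."""
        ds = make_dataset(rng, n_case=50, n_ctrl=50, rho=0.3)
        p1 = coassociation_test(
            ds, "GA", "GB", ResamplingPlan(149, 60, seed=2, perm_mode="numerator_only")
        ).p_perm
        p2 = coassociation_test(
            ds, "GA", "GB", ResamplingPlan(149, 60, seed=2, perm_mode="full_recompute")
        ).p_perm
        assert abs(p1 - p2) < 0.25  # same null decision region, coarser MC noise

    def test_result_records_plan_metadata(self, small_dataset):
        plan = ResamplingPlan(59, 40, seed=4)
        res = coassociation_test(small_dataset, "GA", "GB", plan)
        assert res.n_boot == 40 and res.seed == 4
        assert res.perm_mode == "numerator_only"
        row = res.to_frame()
        assert list(row.columns[:2]) == ["gene_a", "gene_b"]

    def test_loading_tables_have_both_strata(self, small_dataset):
        res = coassociation_test(small_dataset, "GA", "GB", ResamplingPlan(19, 30, seed=1))
        assert set(res.loadings["stratum"]) == {"case", "control"}
        assert (res.loadings["loading_se"] >= 0).all()
        assert len(res.loadings) == 2 * small_dataset.n_snps


def test_dataset_row_order_does_not_change_betas(rng):
    """Shuffling sample rows leaves the observed statistic components intact
    (they are functions of the per-stratum empirical correlations)."""
    ds = make_dataset(rng, n_case=50, n_ctrl=50)
    perm = rng.permutation(ds.n_samples)
    shuffled = GenotypeDataset(
        ds.dosages[perm],
        ds.snp_ids,
        ds.gene_of_snp,
        ds.phenotype[perm],
        [ds.sample_ids[i] for i in perm],
    )
    plan = ResamplingPlan(19, 30, seed=8)
    r1 = coassociation_test(ds, "GA", "GB", plan)
    r2 = coassociation_test(shuffled, "GA", "GB", plan)
    assert r1.beta_case == pytest.approx(r2.beta_case, abs=1e-12)
    assert r1.beta_control == pytest.approx(r2.beta_control, abs=1e-12)
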