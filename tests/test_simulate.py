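"""Simulator: panel LD contract, disease models, presets, provenance."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from coassoc.simulate import (
    DiseaseModel,
    build_population,
    make_synthetic_panel,
    paper_scenarios,
    remove_causal,
    sample_from_population,
    sample_population,
)


class TestSyntheticPanel:
    def test_independent_panel_has_no_ld(self):
        panel = make_synthetic_panel([0.3] * 5, np.eye(5), n_haplotypes=50_000, seed=1)
        np.testing.assert_allclose(panel.empirical_freqs(), 0.3, atol=0.01)
        r = panel.ld_r()
        off = r[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 0.02

    def test_perfect_latent_correlation_duplicates_columns(self):
        sigma = np.ones((2, 2))
        panel = make_synthetic_panel([0.4, 0.4], sigma, n_haplotypes=5000, seed=2)
        np.testing.assert_array_equal(panel.haplotypes[:, 0], panel.haplotypes[:, 1])
        assert panel.ld_r()[0, 1] == pytest.approx(1.0)

    def test_attenuation_matches_orthant_probability(self):
        """Empirical allelic r of an AR(1)-latent pair agrees with the value
        from direct bivariate-normal orthant integration."""
        rho, maf = 0.9, 0.45
        panel = make_synthetic_panel([maf] * 2, ("ar1", rho), n_haplotypes=50_000, seed=3)
        t = norm.ppf(maf)
        p11 = multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]]).cdf([t, t])
        r_expected = (p11 - maf**2) / (maf * (1 - maf))
        r_emp = panel.ld_r()[0, 1]
        assert r_emp == pytest.approx(r_expected, abs=0.05)

    def test_non_psd_rejected_with_eigenvalue(self):
        sigma = np.array([[1.0, 0.9, 0.0], [0.9, 1.0, 0.9], [0.0, 0.9, 1.0]])
        with pytest.raises(ValueError, match="eigenvalue"):
            make_synthetic_panel([0.3] * 3, sigma, 100, seed=0)

    def test_bad_mafs_rejected(self):
        with pytest.raises(ValueError, match="mafs"):
            make_synthetic_panel([0.3, 0.6], np.eye(2), 100, seed=0)


@pytest.fixture(scope="module")
def linked_preset_panel():
    pre = paper_scenarios()["scenario2_7x7"]
    return pre, pre.make_panel(20_000, seed=5)


class TestDiseaseModel:
    def test_scenario_field_validation(self):
        with pytest.raises(ValueError):
            DiseaseModel("type9", "a", "b")
        with pytest.raises(ValueError):
            DiseaseModel("type1", "a", "b", or_interaction=0.8)

    def test_null_model_no_case_control_maf_gap(self, linked_preset_panel):
        pre, panel = linked_preset_panel
        sd = sample_population(panel, pre.make_model(), 100_000, 100_000, seed=6)
        ds = sd.dataset
        case = ds.phenotype == 1
        gap = np.abs(ds.dosages[case].mean(axis=0) - ds.dosages[~case].mean(axis=0)) / 2
        assert gap.max() < 0.01

    def test_prevalence_calibration(self, linked_preset_panel):
        """The root-found intercept reproduces the requested prevalence: for
        a null model it must equal logit(prevalence) up to Monte-Carlo error."""
        pre, panel = linked_preset_panel
        sd = sample_population(panel, pre.make_model(), 500, 500, seed=8)
        beta0 = sd.provenance["beta0"]
        assert beta0 == pytest.approx(np.log(0.1 / 0.9), abs=1e-6)
        m2 = pre.make_model(or_marginal_a=1.3, or_marginal_b=1.7)
        sd2 = sample_population(panel, m2, 500, 500, seed=8)
        # with positive effects the intercept must compensate downwards
        assert sd2.provenance["beta0"] < beta0

    def test_hwe_in_controls(self, linked_preset_panel):
        """Controls track the source population: genotype frequencies at each
        SNP stay within 0.01 of the Hardy-Weinberg expectations computed from
        the panel's empirical allele frequency."""
        pre, panel = linked_preset_panel
        sd = sample_population(panel, pre.make_model(), 5_000, 100_000, seed=7)
        ds = sd.dataset
        controls = ds.dosages[ds.phenotype == 0]
        freqs = panel.empirical_freqs()
        for j, f in enumerate(freqs):
            expected = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
            observed = np.array([(controls[:, j] == g).mean() for g in (0, 1, 2)])
            assert np.abs(observed - expected).max() < 0.01

    def test_determinism(self, linked_preset_panel):
        pre, panel = linked_preset_panel
        m = pre.make_model(or_marginal_a=1.2, or_marginal_b=1.4)
        a = sample_population(panel, m, 500, 500, seed=9)
        b = sample_population(panel, m, 500, 500, seed=9)
        np.testing.assert_array_equal(a.dataset.dosages, b.dataset.dosages)
        np.testing.assert_array_equal(a.dataset.phenotype, b.dataset.phenotype)

    def test_type3_is_individual_level_mixture(self, linked_preset_panel):
        pre3 = paper_scenarios()["scenario3_7x7"]
        _, panel = linked_preset_panel
        m = pre3.make_model(or_interaction=1.3, or_marginal_a=1.3, or_marginal_b=1.7)
        sd = sample_population(panel, m, 400, 400, seed=10)
        assert sd.dataset.n_samples == 800
        assert int(sd.dataset.phenotype.sum()) == 400


class TestPoolSampling:
    def test_balanced_draw(self, linked_preset_panel):
        pre, panel = linked_preset_panel
        pop = build_population(panel, pre.make_model(), 2_000, 2_000, seed=1)
        sd = sample_from_population(pop, 1000, seed=2)
        assert int(sd.dataset.phenotype.sum()) == 500
        assert sd.dataset.n_samples == 1000

    def test_oversized_request_rejected(self, linked_preset_panel):
        pre, panel = linked_preset_panel
        pop = build_population(panel, pre.make_model(), 1_000, 1_000, seed=1)
        with pytest.raises(ValueError, match="pool"):
            sample_from_population(pop, 5000, seed=2)


class TestRemoveCausal:
    def test_counts_and_provenance(self, linked_preset_panel):
        pre, panel = linked_preset_panel
        sd = sample_population(panel, pre.make_model(), 200, 200, seed=3)
        out = remove_causal(sd)
        assert out.dataset.n_snps == sd.dataset.n_snps - 2
        assert out.causal_removed
        assert out.provenance["causal_removed"] == [pre.causal_a, pre.causal_b]
        assert out.provenance["model"]["scenario"] == "type2"

    def test_double_removal_is_error(self, linked_preset_panel):
        pre, panel = linked_preset_panel
        sd = remove_causal(sample_population(panel, pre.make_model(), 200, 200, seed=3))
        with pytest.raises(ValueError, match="already removed"):
            remove_causal(sd)


class TestPresets:
    def test_catalog_structure(self):
        cat = paper_scenarios()
        s1 = cat["scenario1_8x10"]
        sizes = {}
        for s, g in s1.gene_of_snp.items():
            sizes[g] = sizes.get(g, 0) + 1
        assert sorted(sizes.values()) == [8, 10]
        mafs = dict(zip(s1.snp_ids, s1.mafs))
        assert mafs[s1.causal_a] == 0.43 and mafs[s1.causal_b] == 0.44
        s2 = cat["scenario2_7x7"]
        mafs2 = dict(zip(s2.snp_ids, s2.mafs))
        assert mafs2[s2.causal_a] == 0.46 and mafs2[s2.causal_b] == 0.45
        # linked preset has nonzero cross-gene latent correlation
        n_a = sum(1 for g in s2.gene_of_snp.values() if g == s2.gene_a)
        assert np.abs(s2.sigma[:n_a, n_a:]).max() > 0
        assert np.abs(cat["scenario1_8x10"].sigma[:8, 8:]).max() == 0

    @pytest.mark.parametrize("name", sorted(paper_scenarios()))
    def test_every_preset_generates_end_to_end(self, name):
        pre = paper_scenarios()[name]
        panel = pre.make_panel(4_000, seed=1)
        kwargs = {}
        if pre.scenario in ("type1", "type3"):
            kwargs["or_interaction"] = 1.2
        if pre.scenario in ("type2", "type3"):
            kwargs.update(or_marginal_a=1.2, or_marginal_b=1.4)
        sd = remove_causal(sample_population(panel, pre.make_model(**kwargs), 100, 100, seed=2))
        assert sd.dataset.n_samples == 200
        assert set(sd.dataset.genes) == {pre.gene_a, pre.gene_b}
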