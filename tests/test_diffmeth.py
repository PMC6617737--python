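import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ctmeth import diffmeth as dm
from ctmeth import simulate
from ctmeth.io import CountMatrix

from conftest import make_counts, two_group_samples


class TestFilters:
    def test_polymorphic_dyad_rule(self):
        cm = make_counts(N=[[10], [10], [10]], X=[[5], [5], [5]],
                         positions=[100, 200, 300])
        # SNP at the C, at the G (pos+1), and none
        out = dm.filter_polymorphic(cm, {"chr1": [100, 201]})
        assert out.sites["pos"].tolist() == [300]
        # empty SNP set is the identity
        same = dm.filter_polymorphic(cm, {"chr1": []})
        assert same.n_sites == 3

    def test_coverage_rule_boundary(self):
        # 10 samples per group; site0: 8/10 at 20x in both groups (kept),
        # site1: 7/10 in group B (removed at min_fraction=0.8)
        N = np.zeros((2, 20), dtype=int)
        N[0, :8] = 20; N[0, 8:10] = 5
        N[0, 10:18] = 25; N[0, 18:] = 10
        N[1, :8] = 20; N[1, 8:10] = 5
        N[1, 10:17] = 25; N[1, 17:] = 10
        cm = make_counts(N=N, X=np.zeros_like(N))
        groups = {"A": np.arange(20) < 10, "B": np.arange(20) >= 10}
        out = dm.filter_coverage(cm, 20, 0.8, groups)
        assert out.sites["pos"].tolist() == [100]

    def test_permissive_threshold_is_identity(self):
        N = np.array([[1, 30], [8, 0]])
        cm = make_counts(N=N, X=np.zeros_like(N))
        groups = {"all": np.array([True, True])}
        out = dm.filter_coverage(cm, 1, 1e-9, groups)
        assert out.n_sites == 2

    def test_empty_group_rejected(self):
        cm = make_counts(N=[[10, 10]], X=[[0, 0]])
        with pytest.raises(ValueError, match="no samples"):
            dm.filter_coverage(cm, 20, 0.8, {"g": np.array([False, False])})


class TestArcsineTransform:
    def test_midpoint_maps_to_zero(self):
        assert dm.arcsine_transform(np.array(5), np.array(10)) == pytest.approx(0.0)

    def test_monotone_and_bounded(self):
        N = np.full(11, 10)
        X = np.arange(11)
        y = dm.arcsine_transform(X, N)
        assert np.all(np.diff(y) > 0)
        assert np.all(np.abs(y) < np.pi / 2)


class TestSiteTests:
    def test_no_effect_gives_null_stat(self):
        cm = make_counts(N=np.full((1, 8), 10), X=np.full((1, 8), 5))
        samples = two_group_samples(4, 4)
        design = dm.build_design(samples, "cell_type")
        res = dm.site_test_arcsine(cm, design)
        assert res["stat"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_linear_equals_two_sample_t(self):
        """For a two-group design with no covariates, the per-site OLS P
        must equal the textbook pooled two-sample t-test P."""
        rng = np.random.default_rng(0)
        m, n1, n2 = 50, 9, 7
        N = np.full((m, n1 + n2), 30)
        X = rng.binomial(N, 0.6)
        cm = make_counts(N=N, X=X)
        samples = two_group_samples(n1, n2)
        design = dm.build_design(samples, "cell_type")
        res = dm.site_test_linear(cm.fractions(), cm, design)
        frac = cm.fractions()
        ref = stats.ttest_ind(frac[:, n1:], frac[:, :n1], axis=1)
        np.testing.assert_allclose(res["p"].to_numpy(), ref.pvalue, atol=1e-12)
        np.testing.assert_allclose(res["stat"].to_numpy(), ref.statistic,
                                   atol=1e-10)

    def test_linear_recovers_exact_difference(self):
        n = 12
        N = np.full((1, 2 * n), 10)
        X = np.concatenate([np.full(n, 2), np.full(n, 4)])[None, :]
        cm = make_counts(N=N, X=X)
        design = dm.build_design(two_group_samples(n, n), "cell_type")
        res = dm.site_test_linear(cm.fractions(), cm, design)
        # groups at 0.2 vs 0.4 exactly -> coefficient 0.2, but zero residual
        # variance means the site is skipped rather than assigned P=0
        assert np.isnan(res["p"].iloc[0])
        assert res.attrs["skipped"]["zero_residual_variance"] == 1

    def test_planted_large_effect_power(self):
        """Delta = 0.326 at 30x with n=25 vs 20 clears genome-scale
        Bonferroni in nearly all simulated sites."""
        rng = np.random.default_rng(42)
        m, n1, n2 = 1000, 25, 20
        N = np.full((m, n1 + n2), 30)
        p1, p2 = 0.45, 0.45 + 0.326
        X = np.concatenate([rng.binomial(N[:, :n1], p1),
                            rng.binomial(N[:, n1:], p2)], axis=1)
        cm = make_counts(N=N, X=X)
        design = dm.build_design(two_group_samples(n1, n2), "cell_type")
        res = dm.site_test_arcsine(cm, design)
        z_bonf = stats.norm.isf(0.05 / 25e6 / 2)  # genome-scale cutoff
        assert (np.abs(res["stat"]) > z_bonf).mean() >= 0.95

    def test_sign_convention_positive_is_higher_in_alt(self):
        n = 10
        N = np.full((1, 2 * n), 50)
        X = np.concatenate([np.full(n, 10), np.full(n, 40)])[None, :]
        cm = make_counts(N=N, X=X)
        design = dm.build_design(two_group_samples(n, n), "cell_type")
        res = dm.site_test_arcsine(cm, design)
        assert res["stat"].iloc[0] > 0      # OLIG2+ higher
        assert res["direction"].iloc[0] == 1

    def test_sparse_site_skipped(self):
        N = np.array([[10, 10, 0, 0]])
        cm = make_counts(N=N, X=np.zeros_like(N))
        design = dm.build_design(two_group_samples(2, 2), "cell_type")
        res = dm.site_test_arcsine(cm, design)
        assert np.isnan(res["p"].iloc[0])
        assert res.attrs["skipped"]["too_few_per_level"] == 1


@pytest.fixture(scope="module")
def null_binomial(genome, cohort):
    """Null data under the arcsine test's assumed sampling model
    (read-level binomial noise only)."""
    eff = simulate.EffectConfig(frac_celltype_dmp=0.0,
                                n_szdmp_per_celltype=0,
                                n_planted_dmrs=0, individual_sd=1e-4)
    counts, _ = simulate.generate_methylomes(genome, cohort, eff, seed=21)
    return counts


class TestCalibration:
    def test_arcsine_type_i_error_under_binomial_null(self, null_binomial,
                                                      cohort):
        design = dm.build_design(cohort, "cell_type")
        res = dm.site_test_arcsine(null_binomial, design)
        p = res["p"].dropna().to_numpy()
        assert p.size > 5000
        assert 0.04 <= (p < 0.05).mean() <= 0.06
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_linear_type_i_error_under_replicate_null(self, null_methylomes,
                                                      cohort):
        counts, _ = null_methylomes
        design = dm.build_design(cohort, "cell_type")
        res = dm.site_test_linear(counts.fractions(), counts, design)
        p = res["p"].dropna().to_numpy()
        assert 0.04 <= (p < 0.05).mean() <= 0.06
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_tests_agree_in_sign_at_significant_sites(self, methylomes,
                                                      cohort):
        counts, _ = methylomes
        design = dm.build_design(cohort, "cell_type")
        a = dm.site_test_arcsine(counts, design)
        l = dm.site_test_linear(counts.fractions(), counts, design)
        both = (a["p"] < 0.01) & (l["p"] < 0.01)
        agree = np.sign(a.loc[both, "stat"]) == np.sign(l.loc[both, "stat"])
        assert both.sum() > 100
        assert agree.mean() >= 0.99

    def test_low_coverage_small_p_depletion_is_arcsine_specific(self):
        """With replicate variance present, the weighted arcsine test is
        starved of small P at shallow sites relative to deep ones (the
        beta-binomial-style coverage correction); the linear test is
        coverage-blind."""
        rng = np.random.default_rng(3)
        m, n = 4000, 24
        frac = np.clip(rng.normal(0.7, 0.05, size=(m, n)), 0.01, 0.99)
        N = np.where(np.arange(m)[:, None] < m // 2, 3, 30) \
            + np.zeros((m, n), dtype=int)
        X = rng.binomial(N, frac)
        cm = make_counts(N=N, X=X, positions=np.arange(1, m + 1) * 10)
        design = dm.build_design(two_group_samples(12, 12), "cell_type")
        res_a = dm.site_test_arcsine(cm, design)
        res_l = dm.site_test_linear(cm.fractions(), cm, design)
        shallow = np.arange(m) < m // 2
        pa = res_a["p"].to_numpy()
        pl = res_l["p"].to_numpy()
        assert np.nanmean(pa[shallow] < 0.05) < 0.5 * np.nanmean(pa[~shallow] < 0.05)
        assert np.nanmean(pl[shallow] < 0.05) > 0.5 * np.nanmean(pl[~shallow] < 0.05)


class TestAdjustPvalues:
    def test_bh_step_up_by_hand(self):
        out = dm.adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh")
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_bonferroni_identity_and_capping(self):
        assert dm.adjust_pvalues([0.001], "bonferroni")[0] == 0.001
        np.testing.assert_allclose(
            dm.adjust_pvalues([0.5, 0.5], "bonferroni"), [1.0, 1.0])

    def test_stable_under_permutation(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=100)
        perm = rng.permutation(100)
        out = dm.adjust_pvalues(p, "bh")
        out_perm = dm.adjust_pvalues(p[perm], "bh")
        np.testing.assert_allclose(out[perm], out_perm)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            dm.adjust_pvalues([0.1, np.nan], "bh")


class TestBuildDesign:
    def test_reference_levels_and_rank(self, cohort):
        design = dm.build_design(cohort, "cell_type",
                                 ["sex", "age_class", "pc1", "pc2"])
        assert design.columns[0] == "intercept"
        assert design.target == "cell_type[OLIG2+]"
        assert design.group_ref.sum() == 53   # NeuN+ samples
        assert np.linalg.matrix_rank(design.matrix) == design.matrix.shape[1]

    def test_three_level_target_rejected(self, cohort):
        bad = cohort.copy()
        bad.loc[0, "cell_type"] = "other"
        with pytest.raises(ValueError, match="2 levels"):
            dm.build_design(bad, "cell_type")
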