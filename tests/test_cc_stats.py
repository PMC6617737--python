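import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from ctmeth import cc_stats as cs
from ctmeth import diffmeth, simulate


def brute_force_binomial_two_sided(k, n, p=0.5):
    """Oracle: sum the probabilities of all outcomes no more likely than k."""
    probs = np.array([comb(n, i, exact=True) * p**i * (1 - p)**(n - i)
                      for i in range(n + 1)], dtype=float)
    return float(probs[probs <= probs[k] * (1 + 1e-12)].sum())


class TestPermutation:
    def test_group_sizes_and_covariates_preserved(self, cohort):
        perm = cs.permute_diagnosis_labels(cohort, seed=3)
        for ct in ("NeuN+", "OLIG2+"):
            for dx in ("control", "schizophrenia"):
                orig = ((cohort["cell_type"] == ct)
                        & (cohort["diagnosis"] == dx)).sum()
                new = ((perm["cell_type"] == ct)
                       & (perm["diagnosis"] == dx)).sum()
                assert orig == new
        others = [c for c in cohort.columns if c != "diagnosis"]
        pd.testing.assert_frame_equal(perm[others], cohort[others])

    def test_seeded_reproducibility(self, cohort):
        a = cs.permute_diagnosis_labels(cohort, seed=9)
        b = cs.permute_diagnosis_labels(cohort, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_single_diagnosis_rejected(self, cohort):
        mono = cohort.assign(diagnosis="control")
        with pytest.raises(ValueError):
            cs.permute_diagnosis_labels(mono, seed=1)

    def test_zero_permutations_rejected(self, methylomes, cohort):
        counts, _ = methylomes
        with pytest.raises(ValueError):
            cs.permutation_null_run(counts, cohort, n_perm=0)


@pytest.fixture(scope="module")
def small(genome, cohort):
    """A small-site NeuN+ subset so 20+ permutation scans stay fast."""
    eff = simulate.EffectConfig(n_szdmp_per_celltype=30,
                                mean_abs_beta=0.15, beta_halfwidth=0.04)
    counts, truth = simulate.generate_methylomes(genome, cohort, eff,
                                                 seed=41)
    neun = cohort[cohort["cell_type"] == "NeuN+"].reset_index(drop=True)
    idx = [counts.samples.index(s) for s in neun["sample_id"]]
    sub = counts.subset_sites(np.arange(counts.n_sites) < 1500)
    from ctmeth.io import CountMatrix
    cm = CountMatrix(sub.sites, list(neun["sample_id"]),
                     sub.N[:, idx], sub.X[:, idx])
    return cm, neun, truth


class TestPermutationNullRun:
    def test_observed_beats_all_permutations_at_planted_sites(self, small):
        counts, neun, truth = small
        tr = truth.sites.iloc[:1500]
        planted = tr[(tr["is_szdmp"])
                     & (tr["cell_type_of_effect"] == "NeuN+")]
        if len(planted) < 3:
            pytest.skip("no planted NeuN+ szDMPs in the first 1500 sites")
        run = cs.permutation_null_run(counts, neun, n_perm=20, seed=5,
                                      tracked_sites=planted)
        design = diffmeth.build_design(neun, "diagnosis")
        obs = diffmeth.site_test_arcsine(counts, design)
        keys = counts.site_keys()
        loc = keys.get_indexer(pd.Index(zip(planted["chrom"],
                                            planted["pos"])))
        obs_p = obs["p"].to_numpy()[loc]
        # planted effects produce smaller P than nearly every permutation
        frac_beaten = (run.pvalues < obs_p[None, :]).mean()
        assert frac_beaten < 0.2

    def test_null_top_stat_within_permutation_distribution(self, genome,
                                                           cohort):
        eff = simulate.EffectConfig(frac_celltype_dmp=0.0,
                                    n_szdmp_per_celltype=0, n_planted_dmrs=0)
        counts, _ = simulate.generate_methylomes(genome, cohort, eff, seed=43)
        neun = cohort[cohort["cell_type"] == "NeuN+"].reset_index(drop=True)
        idx = [counts.samples.index(s) for s in neun["sample_id"]]
        from ctmeth.io import CountMatrix
        sub = counts.subset_sites(np.arange(counts.n_sites) < 1500)
        cm = CountMatrix(sub.sites, list(neun["sample_id"]),
                         sub.N[:, idx], sub.X[:, idx])
        run = cs.permutation_null_run(cm, neun, n_perm=20, seed=6)
        design = diffmeth.build_design(neun, "diagnosis")
        obs = diffmeth.site_test_arcsine(cm, design)
        obs_top = np.nanquantile(np.abs(obs["stat"]), 0.999)
        emp_p = (run.top_abs_stat >= obs_top).mean()
        assert emp_p > 0.05


class TestBinomialDirectionality:
    @pytest.mark.parametrize("k,n,expected", [
        (13, 14, 0.0018), (63, 83, 2.4e-6), (7, 14, 1.0),
    ])
    def test_reported_anchors(self, k, n, expected):
        assert cs.binomial_two_sided(k, n) == pytest.approx(expected,
                                                            rel=0.05)

    @pytest.mark.parametrize("n", [1, 2, 5, 10, 17, 20])
    def test_matches_brute_force_enumeration(self, n):
        for k in range(n + 1):
            assert cs.binomial_two_sided(k, n) == pytest.approx(
                brute_force_binomial_two_sided(k, n), abs=1e-12)

    def test_doubled_tail_variant(self):
        assert cs.binomial_two_sided(13, 14, method="doubled") \
            == pytest.approx(2 * (comb(14, 14) + comb(14, 13)) / 2**14)

    def test_directionality_on_frames(self):
        res = pd.DataFrame({"direction": [-1] * 13 + [1]})
        n_hypo, n_hyper, frac, p = cs.directionality_test(res)
        assert (n_hypo, n_hyper) == (13, 1)
        assert frac == pytest.approx(13 / 14)
        assert p == pytest.approx(0.0018, rel=0.05)

    def test_empty_selection_rejected(self):
        res = pd.DataFrame({"direction": [0, 0]})
        with pytest.raises(ValueError):
            cs.directionality_test(res)

    def test_planted_directional_bias_recovered(self, methylomes, cohort):
        """Planted szDMP directions (93% hypo NeuN+, 75.9% hyper OLIG2+)
        surface as significant binomial bias in the observed scan."""
        counts, truth = methylomes
        hits = 0
        for ct, expect_hypo in (("NeuN+", True), ("OLIG2+", False)):
            sub = cohort[cohort["cell_type"] == ct].reset_index(drop=True)
            idx = [counts.samples.index(s) for s in sub["sample_id"]]
            from ctmeth.io import CountMatrix
            cm = CountMatrix(counts.sites, list(sub["sample_id"]),
                             counts.N[:, idx], counts.X[:, idx])
            design = diffmeth.build_design(sub, "diagnosis")
            res = diffmeth.site_test_arcsine(cm, design)
            planted = ((truth.sites["is_szdmp"])
                       & (truth.sites["cell_type_of_effect"] == ct)).to_numpy()
            n_hypo, n_hyper, frac, p = cs.directionality_test(
                res, pd.Series(planted))
            if p < 0.05 and ((frac > 0.5) == expect_hypo):
                hits += 1
        assert hits == 2


class TestCellTypeGapReduction:
    def test_constructed_shrinkage_detected(self, genome, cohort):
        """All cell type DMPs NeuN-hyper, all disease effects NeuN-hypo /
        OLIG2-hyper and inside cell type DMPs: every planted disease effect
        pulls the two cell types together, so the control gap must dominate."""
        eff = simulate.EffectConfig(neun_hyper_frac=1.0, neun_hypo_frac=1.0,
                                    olig2_hyper_frac=1.0,
                                    szdmp_in_celltype_dmp_frac=1.0,
                                    mean_abs_beta=0.10, beta_halfwidth=0.04)
        counts, truth = simulate.generate_methylomes(genome, cohort, eff,
                                                     seed=44)
        frac = counts.fractions()
        t = truth.sites
        sz_in_ct = (t["is_szdmp"] & t["is_celltype_dmp"]).to_numpy()
        nondmp = (~t["is_szdmp"] & ~t["is_celltype_dmp"]).to_numpy()
        out = cs.cell_type_difference_reduction(
            frac, cohort,
            {"szdmp": np.flatnonzero(sz_in_ct),
             "background": np.flatnonzero(nondmp)[:2000]})
        sz = out[out["set"] == "szdmp"].iloc[0]
        bg = out[out["set"] == "background"].iloc[0]
        assert sz["fraction_larger_in_controls"] > 0.5
        assert sz["binomial_p"] < 0.05
        assert abs(bg["fraction_larger_in_controls"] - 0.5) < 0.05

    def test_missing_group_rejected(self, methylomes):
        counts, _ = methylomes
        bad = pd.DataFrame({"sample_id": counts.samples,
                            "cell_type": "NeuN+",
                            "diagnosis": "control"})
        with pytest.raises(ValueError):
            cs.cell_type_difference_reduction(counts.fractions(), bad,
                                              {"all": np.arange(3)})


class TestConcordance:
    def _results(self, directions, positions=None):
        n = len(directions)
        pos = positions if positions is not None else np.arange(1, n + 1) * 10
        return pd.DataFrame({"chrom": "chr1", "pos": pos,
                             "direction": directions})

    def test_exact_bin_probability(self):
        """8 of 10 concordant: two-sided exact binomial P = 112/1024."""
        ours = self._results([1] * 10)
        ext = self._results([1] * 8 + [-1] * 2)
        ext["P"] = 0.5
        table = cs.concordance_binned(ours, ext)
        row = table[table["n"] > 0].iloc[0]
        assert row["fraction_concordant"] == pytest.approx(0.8)
        assert row["binomial_p"] == pytest.approx(112 / 1024)

    def test_perfect_external_concordance(self, methylomes, celltype_results):
        _, truth = methylomes
        ref = celltype_results[["chrom", "pos", "direction"]].copy()
        ref = ref[ref["direction"] != 0]
        ext = simulate.generate_external_ewas(ref, 1.0, 3000, seed=7)
        table = cs.concordance_binned(celltype_results, ext)
        filled = table[table["n"] > 0]
        assert (filled["fraction_concordant"] == 1.0).all()

    def test_permuted_labels_center_at_half(self, methylomes, cohort):
        counts, _ = methylomes
        neun = cohort[cohort["cell_type"] == "NeuN+"].reset_index(drop=True)
        idx = [counts.samples.index(s) for s in neun["sample_id"]]
        from ctmeth.io import CountMatrix
        sub = counts.subset_sites(np.arange(counts.n_sites) < 1200)
        cm = CountMatrix(sub.sites, list(neun["sample_id"]),
                         sub.N[:, idx], sub.X[:, idx])
        run = cs.permutation_null_run(cm, neun, n_perm=10, seed=8,
                                      test="linear")
        design = diffmeth.build_design(neun, "diagnosis")
        res = diffmeth.site_test_linear(cm.fractions(), cm, design)
        ref = res[["chrom", "pos", "direction"]].copy()
        ref = ref[ref["direction"] != 0].reset_index(drop=True)
        ext = simulate.generate_external_ewas(ref, 0.9, len(ref), seed=9)
        table = cs.concordance_binned(res, ext, permutation_run=run)
        for _, row in table[table["n"] > 50].iterrows():
            assert abs(np.nanmean(row["perm_fractions"]) - 0.5) < 0.1

    def test_strictly_increasing_edges_required(self):
        ours = self._results([1, 1])
        ext = ours.copy()
        ext["P"] = 0.5
        with pytest.raises(ValueError):
            cs.concordance_binned(ours, ext, bin_edges=[0, 1, 1, 2])


class TestQqSummary:
    def test_uniform_lambda_near_one(self):
        rng = np.random.default_rng(2)
        _, _, lam = cs.qq_summary(rng.uniform(size=20_000))
        assert lam == pytest.approx(1.0, abs=0.05)

    def test_degenerate_and_inflated(self):
        _, _, lam_flat = cs.qq_summary(np.ones(100))
        assert lam_flat == 0.0
        p = np.concatenate([np.full(2000, 1e-6),
                            np.random.default_rng(3).uniform(size=8000)])
        _, _, lam_hot = cs.qq_summary(p)
        assert lam_hot > 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cs.qq_summary([])
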