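"""Neutral-envelope and Bayesian outlier scans, FDR control."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aflpop import outliers
from aflpop.freqs import freq_table_from_counts
from aflpop.outliers import (NeutralCloud, bayesian_scan, bn_freqs,
                             coalescent_scan, envelope_pvalues, fdr_qvalues,
                             neutral_envelope, outlier_report)


class TestBaldingNichols:
    def test_moments(self, rng):
        # mean p_anc, variance p_anc (1 - p_anc) * F
        draws = bn_freqs(np.full(20000, 0.5), 0.039, 1, rng)[0]
        assert draws.mean() == pytest.approx(0.5, abs=0.01)
        assert draws.var() == pytest.approx(0.25 * 0.039, rel=0.05)

    def test_degenerate_fst_zero(self, rng):
        draws = bn_freqs(np.array([0.3, 0.7]), 0.0, 3, rng)
        np.testing.assert_array_equal(draws, [[0.3, 0.7]] * 3)

    def test_invalid_fst(self, rng):
        with pytest.raises(ValueError):
            bn_freqs(np.array([0.5]), 1.5, 2, rng)


class TestNeutralEnvelope:
    def test_island_cloud_self_consistency(self):
        cloud = neutral_envelope("island", 0.03, [30, 30], n_sim=20000, seed=1)
        assert len(cloud.fst) == 20000
        # realized multilocus F_ST within 10% of the requested mean
        assert cloud.mean_fst == pytest.approx(0.03, rel=0.10)

    def test_vanishing_divergence_limit(self):
        cloud = neutral_envelope("island", 1e-4, [30, 30], n_sim=4000,
                                 seed=2, calibrate=False)
        # no divergence: per-locus estimates centered at ~0
        assert abs(np.mean(cloud.fst)) < 0.01

    def test_hierarchical_requires_fct_below_total(self):
        with pytest.raises(ValueError):
            neutral_envelope("hierarchical", 0.03, [30, 30], f_ct=0.05,
                             n_sim=100, seed=0)

    def test_hierarchical_cloud_matches_total(self):
        cloud = neutral_envelope("hierarchical", 0.04, [30, 30], f_ct=0.01,
                                 n_sim=8000, seed=3)
        assert cloud.mean_fst == pytest.approx(0.04, rel=0.10)


class TestEnvelopePvalues:
    def _toy_cloud(self, rng, n=5000, fst_mean=0.05):
        he = rng.uniform(0.05, 0.5, n)
        fst = rng.gamma(2.0, fst_mean / 2.0, n) - 0.02
        return NeutralCloud(he, fst, "island", fst_mean, fst_mean, fst_mean,
                            (30, 30))

    def test_median_gives_half(self, rng):
        cloud = self._toy_cloud(rng)
        med = np.median(cloud.fst)
        p = envelope_pvalues([0.25], [med], cloud, he_bins=1)
        assert p[0] == pytest.approx(0.5, abs=0.02)

    def test_add_one_rule_never_zero(self, rng):
        cloud = self._toy_cloud(rng)
        p = envelope_pvalues([0.25], [10.0], cloud, he_bins=1)
        assert p[0] == pytest.approx(1.0 / (len(cloud.fst) + 1))

    def test_self_calibration_uniform(self, rng):
        # null loci simulated under the same law give uniform p (KS test);
        # the randomized tie rule handles the discreteness of the statistic
        cloud = neutral_envelope("island", 0.04, [30, 30], n_sim=30000, seed=4)
        null = neutral_envelope("island", cloud.param_fst, [30, 30],
                                n_sim=800, seed=5, calibrate=False)
        p = envelope_pvalues(null.he, null.fst, cloud, he_bins=20,
                             tie="randomized", rng=rng)
        assert stats.kstest(p, "uniform").pvalue > 0.01
        # the deterministic mid-p rule is close to calibrated in the mean
        p_mid = envelope_pvalues(null.he, null.fst, cloud, he_bins=20)
        assert p_mid.mean() == pytest.approx(0.5, abs=0.05)

    def test_duplication_invariance(self, rng):
        cloud = self._toy_cloud(rng, n=2000)
        doubled = NeutralCloud(np.r_[cloud.he, cloud.he],
                               np.r_[cloud.fst, cloud.fst], "island",
                               cloud.mean_fst, cloud.target_fst,
                               cloud.param_fst, cloud.sample_sizes)
        he_obs = rng.uniform(0.1, 0.45, 50)
        fst_obs = rng.uniform(0.0, 0.3, 50)
        p1 = envelope_pvalues(he_obs, fst_obs, cloud, he_bins=5)
        p2 = envelope_pvalues(he_obs, fst_obs, doubled, he_bins=5)
        # doubling every simulated locus leaves the ECDF unchanged up to the
        # add-one smoothing term
        np.testing.assert_allclose(p1, p2, atol=2e-3)

    def test_small_bins_merged_with_warning(self, rng):
        cloud = self._toy_cloud(rng, n=300)
        with pytest.warns(UserWarning, match="merged"):
            envelope_pvalues([0.2], [0.05], cloud, he_bins=10, min_bin=100)


class TestFdrQvalues:
    def test_bh_by_hand(self):
        q, flags = fdr_qvalues([0.001, 0.5, 0.9], method="bh")
        np.testing.assert_allclose(q, [0.003, 0.75, 0.9])
        assert flags.tolist() == [True, False, False]

    def test_single_p_of_one(self):
        q, flags = fdr_qvalues([1.0], method="local_fdr")
        assert q[0] == pytest.approx(1.0)
        assert not flags[0]

    def test_all_ones(self):
        q, _ = fdr_qvalues(np.ones(10), method="local_fdr")
        np.testing.assert_allclose(q, 1.0)

    def test_uniform_null_rarely_flagged(self, rng):
        p = rng.uniform(size=1000)
        q_l, f_l = fdr_qvalues(p, method="local_fdr")
        assert f_l.mean() <= 0.01       # local fdr flags ~nothing under null
        q_b, f_b = fdr_qvalues(p, method="bh")
        assert f_b.mean() <= 0.12       # BH flags at most ~10% in expectation

    def test_signal_detected(self, rng):
        p = np.r_[rng.uniform(size=950), rng.uniform(0, 1e-4, 50)]
        q, flags = fdr_qvalues(p, method="local_fdr")
        assert flags[950:].mean() > 0.9
        assert flags[:950].mean() < 0.02

    def test_nan_propagates(self):
        q, flags = fdr_qvalues([0.01, np.nan, 0.5], method="bh")
        assert np.isnan(q[1]) and not flags[1]

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=500)
        q, _ = fdr_qvalues(p, method="local_fdr")
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestBayesianScan:
    def _counts(self, rng, L=60, n=30, fst=0.03, outlier_fst=None):
        p_anc = rng.uniform(0.2, 0.8, L)
        fsts = np.full(L, fst)
        if outlier_fst is not None:
            fsts[0] = outlier_fst
        p = np.empty((2, L))
        for j in range(L):
            p[:, j] = bn_freqs(np.array([p_anc[j]]), fsts[j], 2, rng)[:, 0]
        c0 = rng.binomial(2 * n, p)
        return freq_table_from_counts(["a", "b"], [f"m{j}" for j in range(L)],
                                      c0, np.full((2, L), n))

    def test_null_calibration_matches_prior(self, rng):
        # no locus-specific effects: inclusion stays near the prior 1/11
        ft = self._counts(rng, L=80)
        res = bayesian_scan(ft, n_iter=3000, burn_in=800, thin=4,
                            prior_odds=10.0, seed=1)
        assert np.median(res.posterior_prob) == pytest.approx(1 / 11, abs=0.06)
        assert res.flags.sum() <= 2

    def test_strong_outlier_ranks_top(self, rng):
        ft = self._counts(rng, L=60, fst=0.03, outlier_fst=0.4)
        res = bayesian_scan(ft, n_iter=4000, burn_in=1000, thin=4, seed=2)
        assert res.posterior_prob[0] == res.posterior_prob.max()

    def test_identical_pops_rejects_single_pop(self):
        ft = freq_table_from_counts(["a"], ["m1"], np.array([[10]]),
                                    np.array([[30]]))
        with pytest.raises(ValueError):
            bayesian_scan(ft, n_iter=10, burn_in=2)

    def test_pip_qvalue_construction(self):
        pip = np.array([0.95, 0.9, 0.5, 0.1])
        q = outliers._pip_qvalues(pip)
        np.testing.assert_allclose(
            q, [0.05, 0.075, (0.05 + 0.1 + 0.5) / 3,
                (0.05 + 0.1 + 0.5 + 0.9) / 4])

    def test_pip_monotone_in_true_fst_on_average(self, rng):
        # over the three simulated classes the mean inclusion probability
        # increases with the class differentiation; neutral loci must
        # dominate so the shared beta absorbs only the background level
        L = 300
        p_anc = rng.uniform(0.2, 0.8, L)
        fsts = np.r_[np.full(240, 0.03), np.full(30, 0.11), np.full(30, 0.23)]
        p = np.empty((2, L))
        for j in range(L):
            p[:, j] = bn_freqs(np.array([p_anc[j]]), fsts[j], 2, rng)[:, 0]
        c0 = rng.binomial(60, p)
        ft = freq_table_from_counts(["a", "b"], [f"m{j}" for j in range(L)],
                                    c0, np.full((2, L), 30))
        res = bayesian_scan(ft, n_iter=4000, burn_in=1000, thin=4, seed=3)
        means = [res.posterior_prob[:240].mean(),
                 res.posterior_prob[240:270].mean(),
                 res.posterior_prob[270:].mean()]
        assert means[0] < means[1] < means[2]


class TestReport:
    def test_merge_and_empty(self, rng):
        coa = pd.DataFrame({"marker": ["m1", "m2"], "fst": [0.5, 0.01],
                            "p_value": [0.001, 0.7], "q_value": [0.02, 0.9],
                            "flag_coalescent": [True, False]})
        ft = freq_table_from_counts(["a", "b"], ["m1", "m2"],
                                    np.array([[5, 30], [55, 30]]),
                                    np.full((2, 2), 30))
        bay = bayesian_scan(ft, n_iter=400, burn_in=100, thin=2, seed=1)
        merged = outlier_report(coa, bay)
        assert len(merged) == 2
        assert {"flag_coalescent", "flag_bayesian"} <= set(merged.columns)
        assert outlier_report().empty

    def test_union_of_locus_universes(self):
        coa = pd.DataFrame({"marker": ["m1"], "fst": [0.5],
                            "p_value": [0.001], "q_value": [0.02],
                            "flag_coalescent": [True]})
        chi = pd.DataFrame({"marker": ["m1", "m2"], "chi2": [5.0, np.nan],
                            "p_value": [0.02, np.nan], "exact": [False, False]})
        merged = outlier_report(coalescent=coa, chi2=chi)
        assert len(merged) == 2
        assert np.isnan(merged.loc[merged["marker"] == "m2", "fst"]).all()


class TestFullScan:
    def test_type_one_error_small_on_pure_null(self):
        # full coalescent scan on null data flags well below 2% of loci
        rng = np.random.default_rng(9)
        flagged, total = 0, 0
        for rep in range(3):
            p = bn_freqs(rng.uniform(0.1, 0.9, 600), 0.039, 2, rng)
            c0 = rng.binomial(60, p)
            ft = freq_table_from_counts(
                ["a", "b"], [f"m{j}" for j in range(600)], c0,
                np.full((2, 600), 30))
            scan = coalescent_scan(ft, n_sim=8000, seed=rep)
            flagged += scan["flag_coalescent"].sum()
            total += len(scan)
        assert flagged / total < 0.02
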