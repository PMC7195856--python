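"""Permutation tests, multiple-comparison correction, effect sizes."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from restconn.stats import (chain_adjacency, cluster_permutation_test,
                            cohens_d, correlate_clinical, grid_adjacency,
                            holm_bonferroni, layout_adjacency, no_adjacency,
                            scalar_permutation_test, ttest_power)


class TestPower:
    def test_study_size_reaches_power(self):
        assert ttest_power(101, 84, effect_size=0.5, alpha=0.05) >= 0.9

    def test_power_increases_with_n(self):
        assert ttest_power(20, 20) < ttest_power(100, 100)


class TestHolmBonferroni:
    def test_reported_correction_of_smallest_p(self):
        p = [0.0018, 0.011, 0.18, 0.61]
        corrected = holm_bonferroni(p)
        assert np.isclose(corrected[0], 0.0072)

    def test_single_p_unchanged(self):
        assert holm_bonferroni([0.03])[0] == 0.03

    def test_correction_inflates(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=10)
        assert (holm_bonferroni(p) >= p - 1e-15).all()

    def test_plain_bonferroni_variant(self):
        p = [0.011, 0.2]
        assert np.isclose(holm_bonferroni(p, method="bonferroni")[0], 0.022)

    def test_capped_at_one(self):
        assert (holm_bonferroni([0.9, 0.95, 0.99]) <= 1.0).all()


class TestCohensD:
    def test_equal_means_zero(self):
        assert cohens_d([1, 2, 3], [2, 1, 3]) == 0.0

    def test_unit_effect(self):
        rng = np.random.default_rng(1)
        a = rng.normal(1.0, 1.0, size=100000)
        b = rng.normal(0.0, 1.0, size=100000)
        assert abs(cohens_d(a, b) - 1.0) < 0.02

    def test_t_statistic_identity(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=13)
        b = rng.normal(0.5, size=19)
        t, _ = sps.ttest_ind(a, b)
        d = cohens_d(a, b)
        assert np.isclose(d, t * np.sqrt(1 / 13 + 1 / 19))

    def test_zero_pooled_sd_flagged(self):
        with pytest.warns(UserWarning):
            assert np.isnan(cohens_d([1.0, 1.0], [1.0, 1.0]))


class TestScalarPermutation:
    def test_exhaustive_matches_manual_enumeration(self):
        a = np.array([3.1, 4.5, 2.2])
        b = np.array([6.0, 5.5, 7.1])
        p = scalar_permutation_test(a, b)
        pooled = np.concatenate([a, b])
        t_obs = abs(sps.ttest_ind(a, b)[0])
        count = 0
        for idx in itertools.combinations(range(6), 3):
            ga = pooled[list(idx)]
            gb = pooled[[i for i in range(6) if i not in idx]]
            if abs(sps.ttest_ind(ga, gb)[0]) >= t_obs - 1e-12:
                count += 1
        assert p == count / 20

    def test_identical_constant_groups_give_one(self):
        assert scalar_permutation_test([2.0, 2.0, 2.0], [2.0, 2.0, 2.0]) == 1.0

    def test_huge_shift_reaches_resolution_floor(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.0, 1.0, size=30)
        b = rng.normal(5.0 * np.sqrt(2), 1.0, size=30)
        p = scalar_permutation_test(a, b, n_perm=500, seed=1, exhaustive=False)
        assert p == 1.0 / 501

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(4)
        hits = 0
        n_sim = 500
        for i in range(n_sim):
            a = rng.normal(size=12)
            b = rng.normal(size=12)
            if scalar_permutation_test(a, b, n_perm=200, seed=i,
                                       exhaustive=False) <= 0.05:
                hits += 1
        assert 0.03 <= hits / n_sim <= 0.07


class TestClusterPermutation:
    def test_planted_contiguous_effect_detected(self):
        rng = np.random.default_rng(5)
        n_feat = 30
        a = rng.normal(size=(40, n_feat))
        b = rng.normal(size=(40, n_feat))
        a[:, 10:20] += 1.0
        res = cluster_permutation_test(a, b, chain_adjacency(n_feat),
                                       n_perm=500, seed=0)
        sig = res.significant(0.05)
        assert sig
        members = set(sig[0].members)
        assert len(members & set(range(10, 20))) >= 8

    def test_null_data_reports_extremes_without_clusters(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=(10, 5)) * 0.001
        b = a + 1e-6 * rng.normal(size=(10, 5))
        res = cluster_permutation_test(a, b, chain_adjacency(5), n_perm=200,
                                       seed=1)
        assert np.isfinite(res.max_t) and np.isfinite(res.min_t)
        # weak data: any clusters found must be non-significant
        assert not res.significant(0.05)

    def test_no_adjacency_degenerates_to_max_statistic(self):
        """With no edges every supra-threshold feature is its own cluster,
        equal to a max-|t| single-feature correction."""
        rng = np.random.default_rng(7)
        a = rng.normal(size=(15, 8))
        b = rng.normal(size=(15, 8))
        a[:, 3] += 1.5
        res = cluster_permutation_test(a, b, no_adjacency(8), n_perm=400,
                                       seed=2)
        for c in res.clusters:
            assert len(c.members) == 1
        # oracle: explicit max-|t| permutation correction for feature 3
        x = np.vstack([a, b])
        labels = np.arange(30) < 15
        from restconn.stats import _tstats
        t_obs = _tstats(x, labels)
        tcrit = sps.t.ppf(0.975, 28)
        rng2 = np.random.default_rng(2)
        null = np.zeros(400)
        for i in range(400):
            perm = labels[rng2.permutation(30)]
            t = _tstats(x, perm)
            over = np.abs(t) > tcrit
            null[i] = np.abs(t[over]).max() if over.any() else 0.0
        obs = [c for c in res.clusters if c.members[0] == 3]
        assert obs
        p_oracle = (1 + (null >= abs(obs[0].mass)).sum()) / 401
        assert np.isclose(obs[0].p_value, p_oracle)

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(8)
        hits = 0
        n_sim = 300
        adj = chain_adjacency(10)
        for i in range(n_sim):
            a = rng.normal(size=(15, 10))
            b = rng.normal(size=(15, 10))
            res = cluster_permutation_test(a, b, adj, n_perm=200, seed=i)
            if res.significant(0.05):
                hits += 1
        assert 0.02 <= hits / n_sim <= 0.08

    def test_few_permutations_warn(self):
        rng = np.random.default_rng(9)
        with pytest.warns(UserWarning):
            cluster_permutation_test(rng.normal(size=(5, 4)),
                                     rng.normal(size=(5, 4)),
                                     no_adjacency(4), n_perm=50)


class TestAdjacencyHelpers:
    def test_grid_adjacency_six_connectivity(self):
        pos = np.array([[x, y, z] for x in range(2) for y in range(2)
                        for z in range(2)], dtype=float)
        adj = grid_adjacency(pos).toarray()
        assert adj.sum() // 2 == 12  # edges of a 2x2x2 cube
        np.testing.assert_array_equal(adj, adj.T)

    def test_layout_adjacency_symmetric(self):
        rng = np.random.default_rng(10)
        pos = rng.uniform(size=(20, 2))
        adj = layout_adjacency(pos).toarray()
        np.testing.assert_array_equal(adj, adj.T)
        assert adj.sum() > 0


class TestCorrelateClinical:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        meas = pd.DataFrame({"m": x})
        cov = pd.DataFrame({"c": x})
        row = correlate_clinical(meas, cov).iloc[0]
        assert np.isclose(row.r, 1.0)
        assert row.p_uncorrected < 1e-6

    def test_sign_flips_with_negated_covariate(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=20)
        y = x + rng.normal(size=20)
        r1 = correlate_clinical(pd.DataFrame({"m": x}),
                                pd.DataFrame({"c": y})).iloc[0].r
        r2 = correlate_clinical(pd.DataFrame({"m": x}),
                                pd.DataFrame({"c": -y})).iloc[0].r
        assert np.isclose(r1, -r2)

    def test_missing_values_pairwise_deleted_and_flagged(self):
        meas = pd.DataFrame({"m": [1.0, 2.0, np.nan, 4.0, 5.0]})
        cov = pd.DataFrame({"c": [1.1, 2.2, 3.0, 3.9, np.nan]})
        row = correlate_clinical(meas, cov).iloc[0]
        assert np.isfinite(row.r)  # 3 complete pairs remain
        short = pd.DataFrame({"m": [1.0, np.nan, np.nan, np.nan, 2.0]})
        row2 = correlate_clinical(short, cov).iloc[0]
        assert np.isnan(row2.r)

    def test_band_family_correction(self):
        rng = np.random.default_rng(12)
        meas = pd.DataFrame({f"power_{b}": rng.normal(size=30)
                             for b in ("theta", "alpha", "beta", "gamma")})
        cov = pd.DataFrame({"pain": rng.normal(size=30)})
        table = correlate_clinical(meas, cov,
                                   band_groups={"power": list(meas.columns)})
        assert (table.p_corrected >= table.p_uncorrected - 1e-15).all()

    def test_independent_covariates_uniform_p(self):
        rng = np.random.default_rng(13)
        ps = []
        for _ in range(200):
            m = pd.DataFrame({"m": rng.normal(size=25)})
            c = pd.DataFrame({"c": rng.normal(size=25)})
            ps.append(correlate_clinical(m, c).iloc[0].p_uncorrected)
        # uniformity: mean ~0.5 and ~10% below 0.1
        assert abs(np.mean(ps) - 0.5) < 0.08
        assert abs(np.mean(np.array(ps) < 0.1) - 0.1) < 0.07
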