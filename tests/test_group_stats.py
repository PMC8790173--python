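import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from stimdecode import ConfigurationError, DegenerateDataError
from stimdecode.group_stats import (band_correlation, chance_test,
                                    cluster_permutation, compare_correlations,
                                    dependent_f, fdr, kruskal_wallis,
                                    kruskal_wallis_roi, wilcoxon_posthocs,
                                    wilcoxon_signed_rank)


def _chain_adjacency(n):
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = True
    return adj


class TestDependentF:
    def test_zero_when_classes_identical(self, rng):
        subj = rng.standard_normal((8, 1, 4))
        scores = np.repeat(subj, 3, axis=1)  # same value for all classes
        f = dependent_f(scores)
        assert np.allclose(f, 0.0)

    def test_matches_statsmodels_rm_anova(self, rng):
        from statsmodels.stats.anova import AnovaRM
        import pandas as pd

        x = rng.standard_normal((10, 3))
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(10), 3),
            "protocol": np.tile(["a", "b", "c"], 10),
            "score": x.ravel(),
        })
        res = AnovaRM(df, "score", "subject", within=["protocol"]).fit()
        expected = float(res.anova_table["F Value"].iloc[0])
        ours = dependent_f(x[:, :, None])[0]
        assert ours == pytest.approx(expected, rel=1e-8)


class TestClusterPermutation:
    def test_no_clusters_when_classes_identical(self, rng):
        scores = np.repeat(rng.standard_normal((8, 1, 5)), 3, axis=1)
        res = cluster_permutation(scores, _chain_adjacency(5), n_rand=100,
                                  seed=0)
        assert len(res.clusters) == 0

    def test_planted_contrast_found(self, rng):
        scores = 0.02 * rng.standard_normal((12, 3, 6)) + 1 / 3
        scores[:, 0, 1:3] += 0.15  # class 0 elevated at channels 1-2
        res = cluster_permutation(scores, _chain_adjacency(6), n_rand=200,
                                  seed=0)
        assert len(res.clusters) >= 1
        assert res.mc_p[0] < 0.05
        assert {1, 2} <= set(res.clusters[0].tolist())

    def test_p_values_never_zero(self, rng):
        scores = 0.02 * rng.standard_normal((8, 3, 4)) + 1 / 3
        scores[:, 0] += 1.0  # overwhelming effect
        res = cluster_permutation(scores, _chain_adjacency(4), n_rand=100,
                                  seed=0)
        assert np.all(res.mc_p > 0)
        assert res.mc_p[0] == pytest.approx(1 / 101)

    def test_disconnected_montage_rejected(self, rng):
        adj = np.zeros((4, 4), dtype=bool)
        adj[0, 1] = adj[1, 0] = adj[2, 3] = adj[3, 2] = True
        with pytest.raises(ConfigurationError, match="disconnected"):
            cluster_permutation(rng.standard_normal((8, 3, 4)), adj)

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            cluster_permutation(rng.standard_normal((4, 3, 4)),
                                _chain_adjacency(4))

    def test_low_randomization_warns(self, rng):
        with pytest.warns(UserWarning):
            cluster_permutation(rng.standard_normal((8, 3, 4)),
                                _chain_adjacency(4), n_rand=50, seed=0)


class TestKruskalWallis:
    def test_identical_groups(self):
        g = np.array([1.0, 2.0, 3.0])
        h, p = kruskal_wallis([g, g, g])
        assert h == 0.0 and p == 1.0

    def test_rank_arithmetic_example(self):
        h, p = kruskal_wallis([np.array([1.0, 2, 3]), np.array([4.0, 5, 6]),
                               np.array([7.0, 8, 9])])
        assert h == pytest.approx(7.2)

    def test_strong_separation_significant(self, rng):
        groups = [rng.normal(loc, 0.1, 12) for loc in (0.0, 1.0, 2.0)]
        _, p = kruskal_wallis(groups)
        assert p < 0.01

    def test_roi_family_fdr(self, rng):
        scores = {r: rng.standard_normal((8, 3)) for r in
                  ("M1", "S1", "PMC", "SPL", "IPL")}
        out = kruskal_wallis_roi(scores)
        assert len(out) == 5
        assert (out["p_fdr"] >= out["p_raw"] - 1e-12).all()


class TestWilcoxon:
    def test_all_zero_differences_flagged(self):
        a = np.arange(10.0)
        with pytest.raises(DegenerateDataError):
            wilcoxon_signed_rank(a, a)

    def test_all_positive_differences_give_maximal_z(self):
        # distinct positive differences, no ties: the rank sum is maximal,
        # |Z| = (n(n+1)/2 - mu) / sigma with the untied variance
        n = 24
        b = np.zeros(n)
        a = b + np.linspace(0.5, 2.0, n)
        z, p = wilcoxon_signed_rank(a, b)
        mu = n * (n + 1) / 4
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24)
        expected = (n * (n + 1) / 2 - mu) / sigma
        assert abs(z) == pytest.approx(expected, rel=1e-6)
        assert p < 1e-4

    def test_normal_approximation_close_to_exact_at_n10(self, rng):
        d = rng.standard_normal(10) + 0.5
        while np.any(d == 0):
            d = rng.standard_normal(10) + 0.5
        approx = stats.wilcoxon(d, method="approx", correction=False).pvalue
        exact = stats.wilcoxon(d, method="exact").pvalue
        assert abs(approx - exact) < 0.05

    def test_posthoc_table_fdr_monotone(self, rng):
        scores = rng.standard_normal((12, 3))
        scores[:, 0] += 1.0
        res = wilcoxon_posthocs(scores, ["lMC", "rCB", "sham"])
        assert len(res.table) == 3
        assert (res.table["p_fdr"] >= res.table["p_raw"] - 1e-12).all()


class TestChanceTest:
    def test_uniform_shift_rejects(self, rng):
        f1 = np.full((24, 3), 0.5) + 0.001 * rng.standard_normal((24, 3))
        out = chance_test(f1)
        assert (out["p_fdr"] < 0.001).all()

    def test_exactly_at_chance_flagged(self):
        f1 = np.full((8, 2), 1 / 3)
        out = chance_test(f1)
        assert out["p_raw"].isna().all()

    def test_needs_six_subjects(self, rng):
        with pytest.raises(ConfigurationError):
            chance_test(rng.standard_normal((4, 2)))


class TestCorrelations:
    def test_identity_correlation(self):
        x = np.arange(10.0)
        r, p = band_correlation(x, x)
        assert r == pytest.approx(1.0)

    def test_constant_input_flagged(self):
        with pytest.raises(DegenerateDataError):
            band_correlation(np.ones(10), np.arange(10.0))

    def test_equal_correlations_give_zero_z(self):
        z, p = compare_correlations(0.6, 24, 0.6, 24)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_fisher_z_closed_form(self):
        z, p = compare_correlations(0.85, 24, 0.5, 24)
        expected = (np.arctanh(0.85) - np.arctanh(0.5)) / np.sqrt(2 / 21)
        assert z == pytest.approx(expected)
        assert p == pytest.approx(2 * stats.norm.sf(abs(expected)))

    def test_degenerate_r_rejected(self):
        with pytest.raises(ConfigurationError):
            compare_correlations(1.0, 24, 0.5, 24)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2,
                max_size=20))
def test_fdr_adjusted_monotone_in_raw(p_raw):
    p = np.asarray(p_raw)
    q = fdr(p)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)
    assert np.all(q >= p - 1e-12)
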