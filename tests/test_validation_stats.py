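"""Group tests, correlations, survival models, and embeddings."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protsig import (
    cox_univariate,
    km_logrank,
    pca_report,
    spearman_corr,
    tsne_embed,
    wilcoxon_rank_sum,
)
from protsig.io_preprocess import InputError
from protsig.validation_stats import median_split


def exact_rank_sum_p(x, y):
    """Independent oracle: enumerate every assignment of pooled ranks."""
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    n1 = len(x)
    obs = ranks[:n1].sum()
    sums = np.array([sum(c) for c in itertools.combinations(ranks, n1)])
    lo = np.mean(sums <= obs + 1e-9)
    hi = np.mean(sums >= obs - 1e-9)
    return min(1.0, 2 * min(lo, hi))


class TestWilcoxon:
    def test_extreme_separation_small_sample(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.statistic == 6  # minimum possible rank-sum for group 1
        assert res.p_value == pytest.approx(0.1)

    def test_identical_groups_p_near_one(self):
        res = wilcoxon_rank_sum([1.0, 2.5, 3.5, 7.0] * 5, [1.0, 2.5, 3.5, 7.0] * 5)
        assert res.p_value > 0.9

    def test_large_shift_highly_significant(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 100)
        y = rng.normal(2, 1, 100)
        assert wilcoxon_rank_sum(x, y).p_value < 1e-4

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            wilcoxon_rank_sum([], [1, 2])

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_exact_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(3, 7, size=2)
        x = rng.normal(size=n1)
        y = rng.normal(rng.normal(), 1, size=n2)
        assert wilcoxon_rank_sum(x, y).p_value == pytest.approx(
            exact_rank_sum_p(x, y), abs=1e-12
        )


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman_corr([1, 2, 3, 5], [2, 4, 9, 11]).effect["rho"] == pytest.approx(1.0)

    def test_identical_rankings(self):
        assert spearman_corr([3, 1, 2], [3, 1, 2]).effect["rho"] == pytest.approx(1.0)

    def test_hand_formula_with_one_swap(self):
        # rho = 1 - 6*sum(d^2)/(n(n^2-1)) with sum(d^2)=2 at n=4
        assert spearman_corr([1, 2, 3, 4], [1, 3, 2, 4]).effect["rho"] == pytest.approx(0.8)

    def test_complete_case_drops_missing(self):
        res = spearman_corr([1, 2, 3, 4, np.nan], [1, 2, 3, np.nan, 5])
        assert res.n_used == 3

    def test_constant_vector_undefined(self):
        res = spearman_corr([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(res.effect["rho"])

    @given(st.integers(0, 500))
    @settings(max_examples=20, deadline=None)
    def test_invariance_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        base = spearman_corr(x, y).effect["rho"]
        warped = spearman_corr(np.exp(x), y**3).effect["rho"]
        assert warped == pytest.approx(base, abs=1e-12)


class TestCox:
    def test_null_covariate_recovers_unit_hazard(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(1, 2000)
        x = rng.normal(size=2000)
        res = cox_univariate(t, np.ones(2000), x)
        assert abs(res.effect["coef"]) < 0.1

    def test_binary_flip_inverts_hazard_ratio(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 2, 500)
        t = rng.exponential(1.0 / np.exp(0.7 * x))
        r1 = cox_univariate(t, np.ones(500), x)
        r2 = cox_univariate(t, np.ones(500), 1 - x)
        assert r1.effect["HR"] * r2.effect["HR"] == pytest.approx(1.0, rel=1e-6)

    def test_no_events_rejected(self):
        with pytest.raises(InputError):
            cox_univariate([1, 2, 3], [0, 0, 0], [1, 2, 3])

    def test_monotone_likelihood_path(self):
        """Two subjects, perfect separation: the partial likelihood is
        monotone in beta, so the estimate diverges."""
        res = cox_univariate([1, 2], [1, 1], [1, 0])
        assert res.effect["HR"] > 100


class TestKaplanMeier:
    def test_product_limit_arithmetic(self):
        curves, _ = km_logrank([1, 2, 3, 4, 9, 9, 9, 9], [1] * 8, ["a"] * 4 + ["b"] * 4)
        a = next(c for c in curves if c.label == "a")
        np.testing.assert_allclose(a.survival, [0.75, 0.5, 0.25, 0.0])
        np.testing.assert_allclose(a.at_risk, [4, 3, 2, 1])

    def test_identical_groups_logrank_p_one(self):
        _, lr = km_logrank([1, 2, 3, 4] * 2, [1, 0, 1, 1] * 2, ["a"] * 4 + ["b"] * 4)
        assert lr.p_value == pytest.approx(1.0)

    def test_no_censoring_matches_empirical_survival(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(1, 60)
        curves, _ = km_logrank(
            np.concatenate([t, t + 100]), np.ones(120), ["a"] * 60 + ["b"] * 60
        )
        a = next(c for c in curves if c.label == "a")
        empirical = np.array([(t > ti).mean() for ti in a.times])
        np.testing.assert_allclose(a.survival, empirical, atol=1e-12)

    def test_separated_exponentials_significant(self):
        rng = np.random.default_rng(4)
        t = np.concatenate([rng.exponential(1, 100), rng.exponential(3, 100)])
        _, lr = km_logrank(t, np.ones(200), ["a"] * 100 + ["b"] * 100)
        assert lr.p_value < 0.001

    def test_median_split_balanced(self):
        g = median_split(pd.Series(np.arange(10.0)))
        assert (g == "high").sum() == 5 and (g == "low").sum() == 5


class TestPCA:
    def frame(self, X):
        return pd.DataFrame(X, index=[f"s{i}" for i in range(len(X))],
                            columns=[f"P{j}" for j in range(X.shape[1])])

    def test_isotropic_components_split_evenly(self):
        rng = np.random.default_rng(5)
        rep = pca_report(self.frame(rng.normal(size=(2000, 2))))
        assert rep.variance_pct[0] == pytest.approx(50, abs=5)

    def test_rank_one_data(self):
        x = np.arange(10.0)
        rep = pca_report(self.frame(np.column_stack([x, 2 * x])))
        assert rep.variance_pct[0] == pytest.approx(100, abs=1e-8)

    def test_matches_direct_eigendecomposition(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(300, 6)) @ rng.normal(size=(6, 6))
        rep = pca_report(self.frame(X), standardize=True)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(np.cov(Z.T)))[::-1]
        np.testing.assert_allclose(rep.variance_pct, eig / eig.sum() * 100, atol=1e-10)

    def test_invariant_to_sample_order_and_rescaling(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(100, 4))
        base = pca_report(self.frame(X)).variance_pct
        perm = rng.permutation(100)
        scaled = X[perm] * np.array([3.0, 0.1, 7.0, 1.0]) + 5
        again = pca_report(self.frame(scaled)).variance_pct
        np.testing.assert_allclose(base, again, atol=1e-9)

    def test_variance_percentages_are_a_decreasing_partition(self):
        rng = np.random.default_rng(8)
        rep = pca_report(self.frame(rng.normal(size=(50, 5))))
        pct = rep.variance_pct
        assert (np.diff(pct) <= 1e-9).all() and (pct >= 0).all()
        assert pct.sum() == pytest.approx(100, abs=1e-8)


class TestTsne:
    def clustered(self, n=200, sep=10.0, seed=9):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 5))
        X[n // 2:, 0] += sep
        labels = np.array([0] * (n // 2) + [1] * (n // 2))
        return pd.DataFrame(X, index=[f"s{i}" for i in range(n)],
                            columns=[f"P{j}" for j in range(5)]), labels

    def test_separated_clusters_stay_separated(self):
        from sklearn.metrics import silhouette_score

        df, labels = self.clustered()
        rep = tsne_embed(df, perplexity=20, seed=0)
        assert silhouette_score(rep.coordinates.to_numpy(), labels) > 0.5

    def test_seed_determinism(self):
        df, _ = self.clustered(n=80)
        a = tsne_embed(df, perplexity=10, seed=3).coordinates
        b = tsne_embed(df, perplexity=10, seed=3).coordinates
        pd.testing.assert_frame_equal(a, b)

    def test_perplexity_bound_enforced(self):
        df, _ = self.clustered(n=30)
        with pytest.raises(InputError):
            tsne_embed(df, perplexity=20, seed=0)
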